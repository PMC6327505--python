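"""Deterministic Monod chemostat dynamics.

Single- or multi-strain growth on one limiting substrate under constant
dilution, steady-state analysis, and the volume-change / generation
arithmetic used to index continuous-culture experiments.

State convention: substrate concentration ``S`` (mM) followed by one
biomass concentration per strain (abstract biomass unit; the yield
coefficient carries the unit conversion to mmol substrate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

LN2 = math.log(2.0)

__all__ = [
    "LN2",
    "ChemostatError",
    "WashoutError",
    "InfeasibleFeedError",
    "StrainParams",
    "ChemostatConfig",
    "ReactorState",
    "BiomassEvent",
    "Trajectory",
    "monod_rate",
    "steady_state",
    "simulate",
    "generations_from_volume_changes",
    "volume_changes",
    "generations_to_hours",
    "hours_to_generations",
]


class ChemostatError(ValueError):
    """Invalid chemostat input or configuration."""


class WashoutError(ChemostatError):
    """Dilution rate at or above mu_max: no positive-biomass steady state."""


class InfeasibleFeedError(ChemostatError):
    """Steady-state residual substrate would meet or exceed the feed."""


@dataclass(frozen=True)
class StrainParams:
    """Monod growth parameters of one strain.

    Parameters
    ----------
    name : strain label.
    mu_max : maximal specific growth rate (1/h), > 0.
    K_M : Monod half-saturation constant for the limiting substrate (mM), > 0.
    biomass_yield : biomass formed per mmol substrate consumed, > 0.
    """

    name: str
    mu_max: float
    K_M: float
    biomass_yield: float = 1.0

    def __post_init__(self) -> None:
        if not self.mu_max > 0:
            raise ChemostatError(f"mu_max must be > 0, got {self.mu_max}")
        if not self.K_M > 0:
            raise ChemostatError(f"K_M must be > 0, got {self.K_M}")
        if not self.biomass_yield > 0:
            raise ChemostatError(
                f"biomass_yield must be > 0, got {self.biomass_yield}"
            )


@dataclass(frozen=True)
class ChemostatConfig:
    """Reactor operating point: dilution rate D (1/h), feed substrate
    S_in (mM) and working volume V (mL)."""

    D: float
    S_in: float
    V: float = 60.0

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ChemostatError(f"D must be >= 0, got {self.D}")
        if not self.S_in > 0:
            raise ChemostatError(f"S_in must be > 0, got {self.S_in}")
        if not self.V > 0:
            raise ChemostatError(f"V must be > 0, got {self.V}")


@dataclass(frozen=True)
class ReactorState:
    """Instantaneous reactor state: substrate S (mM) and per-strain biomass."""

    S: float
    x: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.S < 0:
            raise ChemostatError(f"substrate must be >= 0, got {self.S}")
        object.__setattr__(self, "x", tuple(float(v) for v in self.x))
        if any(v < 0 for v in self.x):
            raise ChemostatError(f"biomass must be >= 0, got {self.x}")


@dataclass(frozen=True)
class BiomassEvent:
    """Instantaneous addition of ``amount`` biomass to strain ``strain``
    (name or index) at time ``time`` (h)."""

    time: float
    strain: str | int
    amount: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ChemostatError(f"event time must be >= 0, got {self.time}")
        if self.amount < 0:
            raise ChemostatError(
                f"event amount must be >= 0, got {self.amount}"
            )


@dataclass
class Trajectory:
    """Time-indexed reactor state from a simulation.

    ``X`` has shape (n_times, n_strains), columns ordered as
    ``strain_names``.
    """

    times: np.ndarray
    S: np.ndarray
    X: np.ndarray
    strain_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.times.size:
            self.X = self.X.T
        self.strain_names = tuple(self.strain_names)
        if np.any(np.diff(self.times) <= 0):
            raise ChemostatError("trajectory times must be strictly increasing")
        if self.S.shape != self.times.shape:
            raise ChemostatError("S and times length mismatch")
        if self.X.shape != (self.times.size, len(self.strain_names)):
            raise ChemostatError("X shape does not match times/strain_names")

    @property
    def states(self) -> list[ReactorState]:
        return [
            ReactorState(S=float(s), x=tuple(row))
            for s, row in zip(self.S, self.X)
        ]

    def biomass(self, name: str) -> np.ndarray:
        return self.X[:, self.strain_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        data = {"time_h": self.times, "S_mM": self.S}
        for j, name in enumerate(self.strain_names):
            data[name] = self.X[:, j]
        return pd.DataFrame(data)

    def to_csv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path, comment="#")
        for col in ("time_h", "S_mM"):
            if col not in df.columns:
                raise ChemostatError(f"trajectory file missing column {col!r}")
        names = [c for c in df.columns if c not in ("time_h", "S_mM")]
        return cls(
            times=df["time_h"].to_numpy(),
            S=df["S_mM"].to_numpy(),
            X=df[names].to_numpy(),
            strain_names=tuple(names),
        )


def monod_rate(params: StrainParams, S: float) -> float:
    """Specific growth rate mu_max*S/(K_M+S) at substrate concentration S (mM)."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ChemostatError(f"substrate must be >= 0, got {S}")
    out = params.mu_max * S / (params.K_M + S)
    return float(out) if out.ndim == 0 else out


def steady_state(params: StrainParams, config: ChemostatConfig) -> ReactorState:
    """Positive-biomass steady state of a single strain.

    S* = K_M*D/(mu_max - D), x* = yield*(S_in - S*). Raises
    :class:`WashoutError` when D >= mu_max and :class:`InfeasibleFeedError`
    when S* >= S_in.
    """
    D = config.D
    if D >= params.mu_max:
        raise WashoutError(
            f"D={D} >= mu_max={params.mu_max} for strain {params.name!r}: washout"
        )
    if D <= 0:
        raise ChemostatError(f"steady state requires D > 0, got {D}")
    S_star = params.K_M * D / (params.mu_max - D)
    if S_star >= config.S_in:
        raise InfeasibleFeedError(
            f"residual substrate S*={S_star:.4g} >= feed S_in={config.S_in}"
        )
    x_star = params.biomass_yield * (config.S_in - S_star)
    return ReactorState(S=S_star, x=(x_star,))


def _resolve_strain(strain: str | int, names: Sequence[str]) -> int:
    if isinstance(strain, int):
        if not 0 <= strain < len(names):
            raise ChemostatError(f"strain index {strain} out of range")
        return strain
    try:
        return list(names).index(strain)
    except ValueError:
        raise ChemostatError(f"unknown strain {strain!r}") from None


def simulate(
    strains: StrainParams | Sequence[StrainParams],
    config: ChemostatConfig,
    init: ReactorState,
    t_end: float,
    events: Iterable[BiomassEvent] = (),
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the chemostat ODEs.

    dS/dt = D (S_in - S) - sum_i mu_i(S) x_i / Y_i
    dx_i/dt = (mu_i(S) - D) x_i

    ``events`` add biomass to a strain instantaneously at the stated time.
    A stiff-capable adaptive solver (LSODA) is used; biomass and substrate
    are floored at zero.
    """
    if isinstance(strains, StrainParams):
        strains = [strains]
    strains = list(strains)
    if not strains:
        raise ChemostatError("at least one strain required")
    if t_end <= 0:
        raise ChemostatError(f"t_end must be > 0, got {t_end}")
    names = tuple(p.name for p in strains)
    if len(init.x) != len(strains):
        raise ChemostatError(
            f"init has {len(init.x)} biomass entries for {len(strains)} strains"
        )

    mu_max = np.array([p.mu_max for p in strains])
    K = np.array([p.K_M for p in strains])
    Y = np.array([p.biomass_yield for p in strains])
    D, S_in = config.D, config.S_in

    def rhs(t, y):
        S = y[0] if y[0] > 0 else 0.0
        x = np.clip(y[1:], 0.0, None)
        mu = mu_max * S / (K + S)
        dS = D * (S_in - S) - float(np.dot(mu / Y, x))
        return np.concatenate(([dS], (mu - D) * x))

    evs = sorted(events, key=lambda e: e.time)
    for e in evs:
        _resolve_strain(e.strain, names)
        if e.time > t_end:
            raise ChemostatError(
                f"event at t={e.time} after t_end={t_end}"
            )

    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 201)
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval.size == 0 or t_eval[0] < 0 or t_eval[-1] > t_end:
        raise ChemostatError("t_eval must be non-empty within [0, t_end]")

    y = np.array([init.S, *init.x], dtype=float)
    out_t: list[float] = []
    out_y: list[np.ndarray] = []
    t0 = 0.0
    boundaries = [e.time for e in evs] + [t_end]
    ev_iter = iter(evs)
    next_ev = next(ev_iter, None)
    for t1 in boundaries:
        if t1 > t0:
            seg_mask = (t_eval >= t0) & (t_eval <= t1)
            seg_pts = np.unique(np.concatenate([t_eval[seg_mask], [t0, t1]]))
            sol = solve_ivp(
                rhs, (t0, t1), y, method="LSODA", rtol=rtol, atol=atol,
                t_eval=seg_pts, dense_output=False,
            )
            if not sol.success:
                raise ChemostatError(
                    f"integration failed on [{t0:.4g}, {t1:.4g}]: {sol.message}"
                )
            keep = np.isin(sol.t, t_eval[seg_mask])
            for tt, yy in zip(sol.t[keep], sol.y.T[keep]):
                if out_t and tt <= out_t[-1]:
                    continue
                out_t.append(float(tt))
                out_y.append(np.clip(yy, 0.0, None))
            y = np.clip(sol.y[:, -1], 0.0, None)
        if next_ev is not None and next_ev.time == t1:
            y[1 + _resolve_strain(next_ev.strain, names)] += next_ev.amount
            next_ev = next(ev_iter, None)
        t0 = t1

    Ya = np.array(out_y)
    return Trajectory(
        times=np.array(out_t), S=Ya[:, 0], X=Ya[:, 1:], strain_names=names
    )


def volume_changes(D: float, t: float) -> float:
    """Reactor volume changes accumulated in ``t`` hours at dilution rate D."""
    if D < 0:
        raise ChemostatError(f"D must be >= 0, got {D}")
    if t < 0:
        raise ChemostatError(f"t must be >= 0, got {t}")
    return D * t


def generations_from_volume_changes(vc: float, rounding: str = "truncate"):
    """Population doublings for ``vc`` volume changes: vc/ln 2.

    ``rounding='truncate'`` (default) truncates to an integer,
    ``'exact'`` returns the raw value.
    """
    if vc < 0:
        raise ChemostatError(f"volume changes must be >= 0, got {vc}")
    g = vc / LN2
    if rounding == "truncate":
        return int(g)
    if rounding == "exact":
        return g
    raise ChemostatError(f"unknown rounding mode {rounding!r}")


def generations_to_hours(g: float, D: float) -> float:
    """Hours elapsed after ``g`` doublings at dilution rate D."""
    if D <= 0:
        raise ChemostatError(f"D must be > 0, got {D}")
    return g * LN2 / D


def hours_to_generations(t: float, D: float) -> float:
    """Doublings accumulated after ``t`` hours at dilution rate D."""
    return volume_changes(D, t) / LN2
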