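"""Two-strain competition and wash-in kinetics.

A resident (parent) strain sits at its chemostat steady state; a fitter
variant is introduced at a given time and frequency (or absolute
biomass) and washes in. Provides the per-hour selection rate, the full
ODE wash-in simulation, a closed-form logistic approximation on the
generation axis, and cross-dilution-rate predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chemostat import (
    LN2,
    BiomassEvent,
    ChemostatConfig,
    ChemostatError,
    ReactorState,
    StrainParams,
    Trajectory,
    WashoutError,
    generations_to_hours,
    monod_rate,
    simulate,
    steady_state,
)

__all__ = [
    "EmergenceSpec",
    "FractionSeries",
    "selection_rate",
    "selection_per_generation",
    "simulate_washin",
    "logistic_fraction",
    "time_to_fraction",
    "calibrate_logistic",
    "predict_competition",
    "CompetitionPrediction",
    "crossing_generation",
    "stochastic_emergence_time",
]

_EMERGENCE_MODES = ("frequency", "absolute")
_TIME_UNITS = ("hours", "generations")


@dataclass(frozen=True)
class EmergenceSpec:
    """Deterministic instantaneous introduction of the variant.

    ``amount`` is an initial frequency in (0, 1) in ``mode='frequency'``,
    or an absolute biomass in ``mode='absolute'``. ``t_emerge`` is in
    hours or generations according to ``time_unit``.
    """

    t_emerge: float = 0.0
    amount: float = 1e-6
    mode: str = "frequency"
    time_unit: str = "hours"

    def __post_init__(self) -> None:
        if self.t_emerge < 0:
            raise ChemostatError(f"t_emerge must be >= 0, got {self.t_emerge}")
        if self.mode not in _EMERGENCE_MODES:
            raise ChemostatError(f"unknown emergence mode {self.mode!r}")
        if self.time_unit not in _TIME_UNITS:
            raise ChemostatError(f"unknown time unit {self.time_unit!r}")
        if self.mode == "frequency" and not (0 < self.amount < 1):
            raise ChemostatError(
                f"frequency-mode amount must be in (0,1), got {self.amount}"
            )
        if self.mode == "absolute" and not self.amount > 0:
            raise ChemostatError(
                f"absolute-mode amount must be > 0, got {self.amount}"
            )

    def t_emerge_hours(self, D: float) -> float:
        if self.time_unit == "hours":
            return self.t_emerge
        return generations_to_hours(self.t_emerge, D)


@dataclass
class FractionSeries:
    """Variant frequency vs. generation, optionally with read depth and
    binomial confidence bounds."""

    generations: np.ndarray
    fraction: np.ndarray
    depth: np.ndarray | None = None
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.generations = np.asarray(self.generations, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.generations.shape != self.fraction.shape:
            raise ChemostatError("generations/fraction length mismatch")
        if np.any(np.diff(self.generations) < 0):
            raise ChemostatError("generations must be non-decreasing")
        if np.any((self.fraction < 0) | (self.fraction > 1)):
            raise ChemostatError("fractions must lie in [0, 1]")
        for name in ("depth", "ci_low", "ci_high"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.generations.shape:
                    raise ChemostatError(f"{name} length mismatch")
                setattr(self, name, v)
        if self.ci_low is not None and np.any(self.ci_low > self.fraction + 1e-12):
            raise ChemostatError("ci_low must not exceed fraction")
        if self.ci_high is not None and np.any(self.ci_high < self.fraction - 1e-12):
            raise ChemostatError("ci_high must not be below fraction")

    def __len__(self) -> int:
        return self.generations.size

    def to_frame(self) -> pd.DataFrame:
        data = {"generation": self.generations, "fraction": self.fraction}
        for name, col in (
            ("depth", "depth"), ("ci_low", "ci_low"), ("ci_high", "ci_high")
        ):
            v = getattr(self, name)
            if v is not None:
                data[col] = v
        return pd.DataFrame(data)

    def to_csv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "FractionSeries":
        df = pd.read_csv(path, comment="#")
        for col in ("generation", "fraction"):
            if col not in df.columns:
                raise ChemostatError(
                    f"fraction series file missing column {col!r}"
                )
        kw = {}
        for col in ("depth", "ci_low", "ci_high"):
            if col in df.columns:
                kw[col] = df[col].to_numpy()
        return cls(
            generations=df["generation"].to_numpy(),
            fraction=df["fraction"].to_numpy(),
            **kw,
        )


def selection_rate(
    parent: StrainParams, mutant: StrainParams, config: ChemostatConfig
) -> float:
    """Per-hour growth-rate advantage of the variant invading the
    parent-set steady state: mu_mutant(S*_parent) - D."""
    ss = steady_state(parent, config)  # raises WashoutError if D >= mu_max
    return monod_rate(mutant, ss.S) - config.D


def selection_per_generation(
    parent: StrainParams, mutant: StrainParams, config: ChemostatConfig
) -> float:
    """Per-generation selection coefficient: one generation is one
    doubling at growth rate D, so s_gen = s_hour * ln2 / D."""
    return selection_rate(parent, mutant, config) * LN2 / config.D


def simulate_washin(
    parent: StrainParams,
    mutant: StrainParams,
    config: ChemostatConfig,
    emergence: EmergenceSpec,
    t_end: float,
    t_eval: np.ndarray | None = None,
    n_points: int = 241,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[Trajectory, FractionSeries]:
    """Simulate variant wash-in from the parent steady state.

    Returns the full trajectory (time in hours) and the variant fraction
    on the generation axis (generations = D*t/ln2).
    """
    te = emergence.t_emerge_hours(config.D)
    if te > t_end:
        raise ChemostatError(
            f"emergence at t={te:.4g} h is after t_end={t_end:.4g} h"
        )
    ss = steady_state(parent, config)
    x_p0 = ss.x[0]
    if emergence.mode == "frequency":
        f = emergence.amount
        amount = f / (1.0 - f) * x_p0
    else:
        amount = emergence.amount
    init = ReactorState(S=ss.S, x=(x_p0, 0.0))
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, n_points)
    traj = simulate(
        [parent, mutant], config, init, t_end,
        events=[BiomassEvent(time=te, strain=mutant.name, amount=amount)],
        t_eval=t_eval, rtol=rtol, atol=atol,
    )
    total = traj.X.sum(axis=1)
    frac = np.where(total > 0, traj.X[:, 1] / np.where(total > 0, total, 1.0), 0.0)
    gens = config.D * traj.times / LN2
    return traj, FractionSeries(generations=gens, fraction=frac)


def _logit(f):
    return np.log(f) - np.log1p(-f)


def logistic_fraction(f0: float, s: float, g) -> np.ndarray | float:
    """Closed-form frequency under constant per-generation selection:
    logit f(g) = logit f0 + s*g."""
    if not 0 < f0 < 1:
        raise ChemostatError(
            f"f0 must be strictly inside (0,1), got {f0}"
        )
    g = np.asarray(g, dtype=float)
    z = _logit(f0) + s * g
    out = 1.0 / (1.0 + np.exp(-z))
    return float(out) if out.ndim == 0 else out


def time_to_fraction(f0: float, s: float, target: float) -> float:
    """Generations needed to reach ``target`` frequency from ``f0``."""
    if not 0 < f0 < 1 or not 0 < target < 1:
        raise ChemostatError("frequencies must be strictly inside (0,1)")
    if s == 0:
        raise ChemostatError("s = 0: target is never reached")
    return (_logit(target) - _logit(f0)) / s


def calibrate_logistic(
    g1: float, f1: float, g2: float, f2: float
) -> tuple[float, float]:
    """Solve logit f = logit f0 + s*g through two points.

    Returns (f0 at g=0, s per generation).
    """
    if g1 == g2:
        raise ChemostatError("calibration points must differ in generation")
    for f in (f1, f2):
        if not 0 < f < 1:
            raise ChemostatError("frequencies must be strictly inside (0,1)")
    s = (_logit(f2) - _logit(f1)) / (g2 - g1)
    z0 = _logit(f1) - s * g1
    return 1.0 / (1.0 + np.exp(-z0)), s


def crossing_generation(series: FractionSeries, threshold: float) -> float:
    """First generation at which the fraction reaches ``threshold``
    (linear interpolation); NaN if never reached."""
    f = series.fraction
    g = series.generations
    above = np.nonzero(f >= threshold)[0]
    if above.size == 0:
        return float("nan")
    i = above[0]
    if i == 0 or f[i] == threshold:
        return float(g[i])
    return float(np.interp(threshold, [f[i - 1], f[i]], [g[i - 1], g[i]]))


@dataclass
class CompetitionPrediction:
    """Per-dilution-rate fraction trajectories plus 50% / 97% crossing
    generations."""

    series: dict[float, FractionSeries]
    crossings: pd.DataFrame = field(default_factory=pd.DataFrame)


def predict_competition(
    parent: StrainParams,
    mutant: StrainParams,
    D_list: Sequence[float],
    f0: float = 0.1,
    horizon: float = 445.0,
    S_in: float = 25.0,
    V: float = 60.0,
    n_points: int = 201,
    rtol: float = 1e-8,
) -> CompetitionPrediction:
    """Predict mixed-culture competition outcomes at several dilution rates.

    Both strains start from a mixed steady-state culture (parent-set
    state, variant at frequency ``f0``). ``horizon`` is in generations.
    """
    if not 0 < f0 < 1:
        raise ChemostatError(f"f0 must be in (0,1), got {f0}")
    if horizon < 0:
        raise ChemostatError(f"horizon must be >= 0, got {horizon}")
    limit = min(parent.mu_max, mutant.mu_max)
    series: dict[float, FractionSeries] = {}
    rows = []
    for D in D_list:
        if D >= limit:
            raise WashoutError(
                f"D={D} washes out at least one strain "
                f"(parent mu_max={parent.mu_max}, mutant mu_max={mutant.mu_max})"
            )
        cfg = ChemostatConfig(D=D, S_in=S_in, V=V)
        if horizon == 0:
            fs = FractionSeries(generations=np.array([0.0]),
                                fraction=np.array([f0]))
        else:
            ss = steady_state(parent, cfg)
            x_tot = ss.x[0]
            init = ReactorState(S=ss.S, x=((1 - f0) * x_tot, f0 * x_tot))
            t_end = generations_to_hours(horizon, D)
            traj = simulate(
                [parent, mutant], cfg, init, t_end,
                t_eval=np.linspace(0.0, t_end, n_points), rtol=rtol,
            )
            total = traj.X.sum(axis=1)
            frac = traj.X[:, 1] / total
            fs = FractionSeries(
                generations=D * traj.times / LN2, fraction=np.clip(frac, 0, 1)
            )
        series[D] = fs
        rows.append({
            "D": D,
            "g_half": crossing_generation(fs, 0.5),
            "g_97": crossing_generation(fs, 0.97),
        })
    return CompetitionPrediction(series=series,
                                 crossings=pd.DataFrame(rows))


def stochastic_emergence_time(
    rate_per_hour: float, seed: int | None = None
) -> float:
    """Seeded Poisson-process first-appearance time (exponential waiting
    time). Off by default; deterministic emergence is the standard mode."""
    if not rate_per_hour > 0:
        raise ChemostatError(f"rate must be > 0, got {rate_per_hour}")
    rng = np.random.default_rng(seed)
    return float(rng.exponential(1.0 / rate_per_hour))
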