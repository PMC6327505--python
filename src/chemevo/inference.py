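"""Fitting the wash-in competition model and identifiability diagnostics.

Bounded nonlinear least squares (multi-start, log-parameter space) of the
two-strain chemostat model against observed variant-fraction series,
finite-difference sensitivity / Fisher-information analysis, and seeded
simulate-corrupt-fit parameter-recovery experiments.

Parameter names follow a flat "owner.field" convention:
``parent.mu_max``, ``parent.K_M``, ``parent.yield``, ``mutant.mu_max``,
``mutant.K_M``, ``mutant.yield``, ``emergence.amount``,
``emergence.t_emerge``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .chemostat import ChemostatConfig, ChemostatError, StrainParams
from .competition import EmergenceSpec, FractionSeries, simulate_washin

__all__ = [
    "PARAM_KEYS",
    "RATIO_PAIRS",
    "FitSpec",
    "FitResult",
    "SensitivityReport",
    "WashinModel",
    "fit_washin",
    "sensitivity",
    "recover",
]

PARAM_KEYS = (
    "parent.mu_max",
    "parent.K_M",
    "parent.yield",
    "mutant.mu_max",
    "mutant.K_M",
    "mutant.yield",
    "emergence.amount",
    "emergence.t_emerge",
)

#: Parameter pairs estimable only as ratios from fraction-only data.
RATIO_PAIRS = (
    ("mutant.K_M", "parent.K_M"),
    ("emergence.amount", "parent.yield"),
)

_EPS_DEFAULT = 1e-6


class FitError(ChemostatError):
    """Fit could not be carried out."""


@dataclass
class FitSpec:
    """What to fit and how.

    ``free`` maps parameter names to (low, high) bounds; ``fixed`` holds
    every other model parameter. ``loss`` is "logit" (default; residuals
    on the logit-frequency scale) or "fraction". ``eps`` clips
    frequencies away from {0,1} before the logit.
    """

    free: dict[str, tuple[float, float]]
    fixed: dict[str, float]
    loss: str = "logit"
    weights: np.ndarray | None = None
    eps: float = _EPS_DEFAULT
    n_starts: int = 8
    seed: int = 1363

    def __post_init__(self) -> None:
        if self.loss not in ("logit", "fraction"):
            raise FitError(f"unknown loss {self.loss!r}")
        if not self.free:
            raise FitError("no free parameters: nothing to fit")
        for name, (lo, hi) in self.free.items():
            if name not in PARAM_KEYS:
                raise FitError(f"unknown parameter {name!r}")
            if not lo < hi:
                raise FitError(f"bounds for {name!r} must satisfy low < high")
        missing = set(PARAM_KEYS) - set(self.free) - set(self.fixed)
        if missing:
            raise FitError(
                f"parameters neither free nor fixed: {sorted(missing)}"
            )


class WashinModel:
    """Forward model: parameter dict -> variant fraction (and optionally
    parent+mutant total biomass) at the observation generations.

    By default (``shared_yield=True``) both strains use the parent's
    biomass yield — matching the observation that biomass stays constant
    while the variant washes in — which makes the (parent yield,
    emergence amount) pair exactly ratio-identifiable. Set
    ``shared_yield=False`` to give the variant its own yield.
    """

    def __init__(
        self,
        config: ChemostatConfig,
        generations: np.ndarray,
        emergence_mode: str = "frequency",
        rtol: float = 1e-8,
        shared_yield: bool = True,
    ) -> None:
        self.config = config
        self.generations = np.asarray(generations, dtype=float)
        self.emergence_mode = emergence_mode
        self.rtol = rtol
        self.shared_yield = shared_yield
        # hours corresponding to each observation generation
        self._t_obs = self.generations * math.log(2.0) / config.D
        self._t_end = float(self._t_obs[-1]) if self._t_obs.size else 1.0

    def _simulate(self, params: Mapping[str, float]):
        parent = StrainParams(
            "parent", params["parent.mu_max"], params["parent.K_M"],
            params["parent.yield"],
        )
        mutant_yield = (
            params["parent.yield"] if self.shared_yield
            else params["mutant.yield"]
        )
        mutant = StrainParams(
            "mutant", params["mutant.mu_max"], params["mutant.K_M"],
            mutant_yield,
        )
        emergence = EmergenceSpec(
            t_emerge=params["emergence.t_emerge"],
            amount=params["emergence.amount"],
            mode=self.emergence_mode,
        )
        t_end = max(self._t_end, emergence.t_emerge_hours(self.config.D))
        return simulate_washin(
            parent, mutant, self.config, emergence, t_end,
            t_eval=self._t_obs, rtol=self.rtol,
        )

    def fractions(self, params: Mapping[str, float]) -> np.ndarray:
        _, fs = self._simulate(params)
        return fs.fraction

    def fractions_and_biomass(
        self, params: Mapping[str, float]
    ) -> tuple[np.ndarray, np.ndarray]:
        traj, fs = self._simulate(params)
        return fs.fraction, traj.X.sum(axis=1)


@dataclass
class FitResult:
    """Best-of-multi-start least-squares estimate."""

    estimates: dict[str, float]
    residual_sum: float
    covariance: np.ndarray
    covariance_singular: bool
    identifiable_combos: list[tuple[str, ...]]
    n_obs: int
    free_names: tuple[str, ...]
    start_costs: tuple[float, ...] = ()

    def stderr(self, name: str) -> float:
        i = self.free_names.index(name)
        return float(np.sqrt(max(self.covariance[i, i], 0.0)))


@dataclass
class SensitivityReport:
    """Finite-difference Jacobian (w.r.t. log parameters), FIM = J^T J
    and its eigen-structure. Eigenvalues are sorted descending;
    eigenvector ``i`` is ``eigenvectors[:, i]``."""

    free_names: tuple[str, ...]
    jacobian: np.ndarray
    fim: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    near_null_directions: list[np.ndarray]
    threshold: float

    @property
    def condition_number(self) -> float:
        lam = self.eigenvalues
        return float(lam[0] / lam[-1]) if lam[-1] > 0 else float("inf")


def _logit(f: np.ndarray, eps: float) -> np.ndarray:
    f = np.clip(f, eps, 1.0 - eps)
    return np.log(f) - np.log1p(-f)


def _residual_fn(
    model: WashinModel, data: FractionSeries, spec: FitSpec,
    free_names: Sequence[str],
) -> Callable[[np.ndarray], np.ndarray]:
    obs = data.fraction
    w = np.ones_like(obs) if spec.weights is None else np.sqrt(spec.weights)
    if spec.loss == "logit":
        obs_t = _logit(obs, spec.eps)

    def residuals(theta: np.ndarray) -> np.ndarray:
        params = dict(spec.fixed)
        params.update(
            {n: math.exp(t) for n, t in zip(free_names, theta)}
        )
        pred = model.fractions(params)
        if spec.loss == "logit":
            r = _logit(pred, spec.eps) - obs_t
        else:
            r = pred - obs
        return w * r

    return residuals


def fit_washin(
    data: FractionSeries,
    spec: FitSpec,
    config: ChemostatConfig,
    emergence_mode: str = "frequency",
    rtol: float = 1e-8,
    combo_threshold: float = 3e-6,
) -> FitResult:
    """Fit the wash-in model to an observed fraction series.

    Bounded least squares on log-parameters with Latin-hypercube
    multi-start (deterministic for a given ``spec.seed``). The returned
    covariance is on the natural parameter scale (delta method from the
    log-scale J^T J); it is flagged singular when the information matrix
    is ill-conditioned, and ``identifiable_combos`` lists parameter sets
    constrained only in combination (near-null FIM directions).
    """
    if len(data) < 2:
        raise FitError(f"need >= 2 observations, got {len(data)}")
    free_names = tuple(sorted(spec.free))
    model = WashinModel(config, data.generations, emergence_mode, rtol=rtol)
    residuals = _residual_fn(model, data, spec, free_names)

    lo = np.log([spec.free[n][0] for n in free_names])
    hi = np.log([spec.free[n][1] for n in free_names])
    sampler = qmc.LatinHypercube(d=len(free_names), seed=spec.seed)
    starts = [0.5 * (lo + hi)]
    if spec.n_starts > 1:
        u = sampler.random(spec.n_starts - 1)
        starts.extend(lo + u * (hi - lo))

    best = None
    start_costs = []
    for x0 in starts:
        try:
            res = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                x_scale="jac",
            )
        except (ValueError, FloatingPointError):
            start_costs.append(float("inf"))
            continue
        if not np.isfinite(res.cost):
            start_costs.append(float("inf"))
            continue
        start_costs.append(float(res.cost))
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("loss non-finite at every start")

    theta = best.x
    estimates = {n: float(math.exp(t)) for n, t in zip(free_names, theta)}
    rss = float(2.0 * best.cost)
    n, p = len(data), len(free_names)

    J = best.jac  # d residual / d log-param
    JTJ = J.T @ J
    sigma2 = rss / max(n - p, 1)
    cond = np.linalg.cond(JTJ)
    singular = not np.isfinite(cond) or cond > 1e10
    cov_log = sigma2 * np.linalg.pinv(JTJ)
    scale = np.array([estimates[nm] for nm in free_names])
    covariance = cov_log * np.outer(scale, scale)

    params_opt = dict(spec.fixed)
    params_opt.update(estimates)
    sens = sensitivity(
        model.fractions, params_opt, free_names, threshold=combo_threshold
    )
    combos = _combos_from_directions(sens, free_names)
    singular = singular or bool(combos)

    return FitResult(
        estimates=estimates,
        residual_sum=rss,
        covariance=covariance,
        covariance_singular=singular,
        identifiable_combos=combos,
        n_obs=n,
        free_names=free_names,
        start_costs=tuple(start_costs),
    )


def _combos_from_directions(
    report: SensitivityReport, free_names: Sequence[str],
    component_cutoff: float = 0.3,
) -> list[tuple[str, ...]]:
    combos = []
    for v in report.near_null_directions:
        names = tuple(
            sorted(n for n, c in zip(free_names, v) if abs(c) >= component_cutoff)
        )
        if len(names) >= 2 and names not in combos:
            combos.append(names)
    return combos


def sensitivity(
    model_fn: Callable[[Mapping[str, float]], np.ndarray],
    params: Mapping[str, float],
    free_names: Sequence[str],
    perturbation: float = 0.01,
    threshold: float = 1e-6,
) -> SensitivityReport:
    """Central finite-difference sensitivity of ``model_fn`` outputs
    w.r.t. the log of each free parameter, with FIM eigen-analysis.

    ``near_null_directions`` are eigenvectors whose eigenvalue falls
    below ``threshold`` times the leading eigenvalue — parameter
    combinations the observations do not constrain.
    """
    if not 0 < perturbation <= 0.1:
        raise ChemostatError(
            f"perturbation must be in (0, 0.1], got {perturbation}"
        )
    free_names = tuple(free_names)
    base = dict(params)
    cols = []
    for name in free_names:
        up = dict(base)
        dn = dict(base)
        up[name] = base[name] * math.exp(perturbation)
        dn[name] = base[name] * math.exp(-perturbation)
        cols.append((model_fn(up) - model_fn(dn)) / (2.0 * perturbation))
    J = np.column_stack(cols)
    if not np.any(J):
        raise ChemostatError(
            "sensitivity step underflow: perturbed outputs identical"
        )
    fim = J.T @ J
    lam, vec = np.linalg.eigh(fim)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    lam = np.clip(lam, 0.0, None)
    near_null = [vec[:, i] for i in range(len(lam))
                 if lam[i] < threshold * lam[0]]
    return SensitivityReport(
        free_names=free_names, jacobian=J, fim=fim,
        eigenvalues=lam, eigenvectors=vec,
        near_null_directions=near_null, threshold=threshold,
    )


def recover(
    truth: Mapping[str, float],
    spec: FitSpec,
    config: ChemostatConfig,
    depth: int = 1000,
    n_reps: int = 20,
    seed: int = 0,
    generations: np.ndarray | None = None,
    emergence_mode: str = "frequency",
    rtol: float = 1e-8,
) -> pd.DataFrame:
    """Seeded simulate -> binomial-corrupt -> fit recovery experiment.

    Returns one row per quantity (each free parameter plus any
    documented ratio pair with both members free) with columns
    ``truth, mean_est, bias_rel, rmse_rel, se_med, mc_sd, n_ok,
    nonidentifiable_frac``. Individual fit failures are recorded, not
    fatal.
    """
    if n_reps < 1:
        raise ChemostatError(f"n_reps must be >= 1, got {n_reps}")
    if depth < 1:
        raise ChemostatError(f"depth must be >= 1, got {depth}")
    if generations is None:
        generations = np.arange(0.0, 445.0 + 1e-9, 20.0)
    generations = np.asarray(generations, dtype=float)
    model = WashinModel(config, generations, emergence_mode, rtol=rtol)
    truth = dict(truth)
    f_true = model.fractions(truth)
    rng = np.random.default_rng(seed)

    ratio_quants = [
        (f"{a}/{b}", a, b) for a, b in RATIO_PAIRS
        if a in spec.free and b in spec.free
    ]
    est_rows = []
    se_rows = []
    flagged = 0
    n_fail = 0
    for _ in range(n_reps):
        counts = rng.binomial(depth, f_true)
        obs = counts / depth
        data = FractionSeries(
            generations=generations, fraction=obs,
            depth=np.full_like(generations, float(depth)),
        )
        rep_spec = FitSpec(
            free=dict(spec.free), fixed=dict(spec.fixed), loss=spec.loss,
            eps=max(spec.eps, 0.5 / depth) if spec.loss == "logit" else spec.eps,
            n_starts=spec.n_starts, seed=spec.seed,
        )
        try:
            fit = fit_washin(data, rep_spec, config, emergence_mode, rtol=rtol)
        except FitError:
            n_fail += 1
            continue
        row = dict(fit.estimates)
        ses = {n: fit.stderr(n) for n in fit.free_names}
        for qname, a, b in ratio_quants:
            row[qname] = fit.estimates[a] / fit.estimates[b]
            ia, ib = fit.free_names.index(a), fit.free_names.index(b)
            # delta method on the log scale for the ratio
            va = fit.covariance[ia, ia] / fit.estimates[a] ** 2
            vb = fit.covariance[ib, ib] / fit.estimates[b] ** 2
            cab = fit.covariance[ia, ib] / (fit.estimates[a] * fit.estimates[b])
            var_log = max(va + vb - 2 * cab, 0.0)
            ses[qname] = row[qname] * math.sqrt(var_log)
        if any(
            set(pair) <= set(c)
            for c in fit.identifiable_combos for pair in RATIO_PAIRS
        ):
            flagged += 1
        est_rows.append(row)
        se_rows.append(ses)

    if not est_rows:
        raise FitError(f"all {n_reps} replicate fits failed")
    est = pd.DataFrame(est_rows)
    se = pd.DataFrame(se_rows)

    quantities = list(sorted(spec.free)) + [q for q, _, _ in ratio_quants]
    truth_vals = dict(truth)
    for qname, a, b in ratio_quants:
        truth_vals[qname] = truth[a] / truth[b]
    out = []
    n_ok = len(est_rows)
    for q in quantities:
        tv = truth_vals[q]
        e = est[q].to_numpy()
        out.append({
            "quantity": q,
            "truth": tv,
            "mean_est": float(np.mean(e)),
            "bias_rel": float((np.mean(e) - tv) / tv),
            "rmse_rel": float(np.sqrt(np.mean((e - tv) ** 2)) / tv),
            "se_med": float(np.median(se[q])),
            "mc_sd": float(np.std(e, ddof=1)) if n_ok > 1 else float("nan"),
            "n_ok": n_ok,
            "n_fail": n_fail,
            "nonidentifiable_frac": flagged / n_ok,
        })
    return pd.DataFrame(out).set_index("quantity")
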