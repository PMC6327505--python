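"""Seeded synthetic-data generators.

Emulate the measurements of a chemostat evolution experiment so every
analysis stage can be exercised without external data: deterministic
Monod trajectories with multiplicative lognormal concentration noise,
multinomial sequencing-depth noise on variant fractions, noisy
Michaelis-Menten uptake curves, and promoter sequences with planted
degenerate-consensus sites. All generators are pure functions of
(config, seed) and ship a truth record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chemostat import LN2, ChemostatConfig, ChemostatError, StrainParams
from .competition import EmergenceSpec, FractionSeries, simulate_washin
from .cre import reverse_complement

__all__ = [
    "ScenarioConfig",
    "EvolutionDataset",
    "default_scenario",
    "generate_evolution_dataset",
    "generate_pyroseq_counts",
    "generate_promoters",
    "generate_uptake_data",
    "PARENT_PRODUCT_YIELD",
    "EVOLVED_PRODUCT_YIELD",
]

# Per-glucose product yields (mol/mol) used for the emulated metabolite
# profiles: resident strain is homolactic-dominant (lactate:acetate 16),
# the evolved strain mixed-acid-shifted (ratio 7) with pyruvate overflow.
PARENT_PRODUCT_YIELD = {
    "lactate": 16.0 / 9.0, "acetate": 1.0 / 9.0, "ethanol": 1.0 / 9.0,
    "formate": 2.0 / 9.0, "pyruvate": 0.0,
}
EVOLVED_PRODUCT_YIELD = {
    "lactate": 1.4, "acetate": 0.2, "ethanol": 0.2,
    "formate": 0.4, "pyruvate": 0.2,
}


@dataclass
class ScenarioConfig:
    """Everything needed to emulate one evolution experiment."""

    parent: StrainParams
    mutant: StrainParams
    chemostat: ChemostatConfig
    emergence: EmergenceSpec
    sample_every: float = 20.0
    horizon_generations: float = 445.0
    conc_cv: float = 0.05
    depth: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ChemostatError(f"depth must be >= 1, got {self.depth}")
        if self.conc_cv < 0:
            raise ChemostatError(f"conc_cv must be >= 0, got {self.conc_cv}")
        if not 0 < self.sample_every <= self.horizon_generations:
            raise ChemostatError("sampling grid must lie within the horizon")

    @property
    def sample_generations(self) -> np.ndarray:
        return np.arange(
            0.0, self.horizon_generations + 1e-9, self.sample_every
        )


def default_scenario(seed: int = 0, depth: int = 500,
                     conc_cv: float = 0.05) -> ScenarioConfig:
    """Two-strain default: resident (mu_max 0.7/h, K_M 0.1 mM) versus an
    evolved variant (mu_max 0.55/h, K_M 0.01 mM), equal yields, D=0.5/h,
    25 mM glucose feed. The emergence frequency is set so the variant
    passes 1% around generation 75 and 50% around generation 190, and
    exceeds 97% well before generation 445."""
    return ScenarioConfig(
        parent=StrainParams("parent", 0.7, 0.1, 1.0),
        mutant=StrainParams("evolved", 0.55, 0.01, 1.0),
        chemostat=ChemostatConfig(D=0.5, S_in=25.0, V=60.0),
        emergence=EmergenceSpec(t_emerge=0.0, amount=5e-4, mode="frequency"),
        depth=depth, conc_cv=conc_cv, seed=seed,
    )


@dataclass
class EvolutionDataset:
    """Generated observations plus the truth record that produced them."""

    biomass: pd.DataFrame
    metabolites: pd.DataFrame
    pyroseq: pd.DataFrame
    fractions: FractionSeries
    truth: dict = field(default_factory=dict)


def generate_evolution_dataset(config: ScenarioConfig) -> EvolutionDataset:
    """Emulate one evolution experiment.

    True fractions come from the ODE wash-in model; observed variant
    read counts are Binomial(depth, fraction); biomass and metabolite
    concentrations carry multiplicative lognormal noise of the stated
    CV. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    gens = config.sample_generations
    D = config.chemostat.D
    t_end = float(gens[-1]) * LN2 / D
    traj, fs_true = simulate_washin(
        config.parent, config.mutant, config.chemostat, config.emergence,
        t_end=t_end, t_eval=gens * LN2 / D,
    )
    f_true = fs_true.fraction
    total_x = traj.X.sum(axis=1)

    sigma = np.sqrt(np.log1p(config.conc_cv ** 2))

    def noisy(truth: np.ndarray) -> np.ndarray:
        if sigma == 0:
            return truth.copy()
        return truth * rng.lognormal(mean=0.0, sigma=sigma, size=truth.shape)

    biomass = pd.DataFrame({
        "generation": gens, "biomass": noisy(total_x),
    })

    consumed = 2.0 * (config.chemostat.S_in - traj.S)  # mM pyruvate equiv / 2
    met_cols = {"generation": gens}
    for met in ("lactate", "acetate", "ethanol", "formate", "pyruvate"):
        y = ((1.0 - f_true) * PARENT_PRODUCT_YIELD[met]
             + f_true * EVOLVED_PRODUCT_YIELD[met])
        met_cols[met] = noisy(0.5 * consumed * y)
    metabolites = pd.DataFrame(met_cols)

    counts = rng.binomial(config.depth, f_true)
    obs_frac = counts / config.depth
    half_width = 1.96 * np.sqrt(
        np.clip(obs_frac * (1 - obs_frac), 0.0, None) / config.depth
    )
    fractions = FractionSeries(
        generations=gens, fraction=obs_frac,
        depth=np.full_like(gens, float(config.depth)),
        ci_low=np.clip(obs_frac - half_width, 0.0, 1.0),
        ci_high=np.clip(obs_frac + half_width, 0.0, 1.0),
    )
    pyroseq = pd.DataFrame({
        "generation": gens,
        "depth": np.full_like(gens, float(config.depth)),
        "count_wildtype": config.depth - counts,
        "count_variant": counts,
    })

    truth = {
        "parent.mu_max": config.parent.mu_max,
        "parent.K_M": config.parent.K_M,
        "parent.yield": config.parent.biomass_yield,
        "mutant.mu_max": config.mutant.mu_max,
        "mutant.K_M": config.mutant.K_M,
        "mutant.yield": config.mutant.biomass_yield,
        "emergence.amount": config.emergence.amount,
        "emergence.t_emerge": config.emergence.t_emerge,
        "emergence.mode": config.emergence.mode,
        "D": D,
        "S_in": config.chemostat.S_in,
        "depth": config.depth,
        "conc_cv": config.conc_cv,
        "seed": config.seed,
        "generations": gens,
        "fraction_true": f_true,
        "biomass_true": total_x,
    }
    return EvolutionDataset(
        biomass=biomass, metabolites=metabolites, pyroseq=pyroseq,
        fractions=fractions, truth=truth,
    )


def generate_pyroseq_counts(
    fractions: Sequence[float], depth: int, seed: int | None = 0
) -> np.ndarray:
    """Multinomial read counts for >= 2 variant frequencies summing to 1."""
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions < 0):
        raise ChemostatError("variant frequencies must be >= 0")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ChemostatError(
            f"frequencies must sum to 1, got {fractions.sum()!r}"
        )
    if depth < 1:
        raise ChemostatError(f"depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    return rng.multinomial(depth, fractions / fractions.sum())


def generate_promoters(
    n: int,
    length: int,
    planted: Sequence[tuple[int, str, int, str]] = (),
    gc: float = 0.5,
    seed: int | None = 0,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """i.i.d. background sequences with exactly written planted sites.

    ``planted`` entries are (sequence index, site, 0-based start,
    strand); '-' strand sites are written as their reverse complement on
    the forward strand. Returns FASTA records plus a truth table with
    columns seq_id, start, end, strand, site_seq. Overlapping planted
    sites are rejected.
    """
    if n < 0 or length < 1:
        raise ChemostatError("need n >= 0 sequences of length >= 1")
    if not 0 < gc < 1:
        raise ChemostatError(f"gc must be in (0,1), got {gc}")
    intervals: dict[int, list[tuple[int, int]]] = {}
    for idx, site, pos, strand in planted:
        if not 0 <= idx < n:
            raise ChemostatError(f"planted sequence index {idx} out of range")
        if strand not in "+-":
            raise ChemostatError(f"strand must be '+' or '-', got {strand!r}")
        if pos < 0 or pos + len(site) > length:
            raise ChemostatError(
                f"planted site at {pos} does not fit in length {length}"
            )
        for a, b in intervals.get(idx, []):
            if pos < b and a < pos + len(site):
                raise ChemostatError(
                    f"overlapping planted sites on sequence {idx}"
                )
        intervals.setdefault(idx, []).append((pos, pos + len(site)))

    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    records = []
    rows = []
    for i in range(n):
        bases = rng.choice(list("ACGT"), size=length, p=p)
        seq_id = f"promoter_{i:03d}"
        for idx, site, pos, strand in planted:
            if idx != i:
                continue
            written = site.upper() if strand == "+" else reverse_complement(site)
            bases[pos:pos + len(site)] = list(written)
            rows.append({
                "seq_id": seq_id, "start": pos, "end": pos + len(site),
                "strand": strand, "site_seq": site.upper(),
            })
        records.append(SeqRecord(
            Seq("".join(bases)), id=seq_id, description=""
        ))
    truth = pd.DataFrame(
        rows, columns=["seq_id", "start", "end", "strand", "site_seq"]
    )
    return records, truth


def generate_uptake_data(
    Vmax: float,
    Km: float,
    S_levels: Sequence[float] = (1.2, 2.5, 5.0, 10.0, 25.0, 50.0, 100.0, 200.0),
    cv: float = 0.0,
    replicates: int = 1,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, dict]:
    """Michaelis-Menten uptake measurements with multiplicative
    lognormal noise. Returns a (S_uM, v) table plus the truth record."""
    S_levels = np.asarray(S_levels, dtype=float)
    if np.any(S_levels <= 0):
        raise ChemostatError("S_levels must be > 0")
    if replicates < 1:
        raise ChemostatError(f"replicates must be >= 1, got {replicates}")
    if cv < 0:
        raise ChemostatError(f"cv must be >= 0, got {cv}")
    rng = np.random.default_rng(seed)
    S = np.tile(S_levels, replicates)
    v_true = Vmax * S / (Km + S)
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv ** 2))
        v = v_true * rng.lognormal(0.0, sigma, size=S.shape)
    else:
        v = v_true.copy()
    table = pd.DataFrame({"S_uM": S, "v": v})
    truth = {"Vmax": Vmax, "Km": Km, "cv": cv,
             "replicates": replicates, "seed": seed}
    return table, truth
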