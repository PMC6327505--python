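"""Scalar physiology and genomics computations.

Specific fermentation fluxes from chemostat concentrations,
homolactic / mixed-acid stoichiometry with ATP accounting, spontaneous
mutation-rate arithmetic, Michaelis-Menten uptake-kinetics fitting, and
codon-level SNP annotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from scipy import stats
from scipy.optimize import curve_fit

from .chemostat import ChemostatError

__all__ = [
    "FluxRecord",
    "FermentationMetrics",
    "FermentationStoichiometry",
    "HOMOLACTIC",
    "MIXED_ACID",
    "SNPRecord",
    "SNPAnnotation",
    "specific_flux",
    "fermentation_metrics",
    "atp_yield",
    "atp_percent_increase",
    "mutation_rate",
    "fit_uptake_kinetics",
    "UptakeFit",
    "annotate_snp",
]

METABOLITES = ("glucose", "lactate", "acetate", "formate", "ethanol", "pyruvate")

#: genome size used for mutation-rate arithmetic (bp), overridable
DEFAULT_GENOME_LENGTH = 2.5e6

#: lactate:acetate ratio separating the two fermentation-mode labels
MODE_RATIO_THRESHOLD = 10.0


@dataclass
class FluxRecord:
    """Named specific rates (mmol per biomass-unit per hour).

    Products carry positive sign; substrate consumption is reported as
    positive uptake (``uptake=True`` entries were sign-flipped).
    """

    q: dict[str, float]
    carbon_recovery: float | None = None

    @property
    def lactate_acetate_ratio(self) -> float:
        return fermentation_metrics(self).ratio


@dataclass(frozen=True)
class FermentationMetrics:
    ratio: float
    mode: str


def specific_flux(
    D: float, c_out: float, c_in: float, X: float, as_uptake: bool = False
) -> float:
    """Specific production rate q = D*(c_out - c_in)/X.

    With ``as_uptake=True`` the sign is flipped so consumption of a
    substrate (c_in > c_out) reads as a positive uptake rate.
    """
    if not X > 0:
        raise ChemostatError(f"biomass must be > 0, got {X}")
    if D < 0:
        raise ChemostatError(f"D must be >= 0, got {D}")
    q = D * (c_out - c_in) / X
    return -q if as_uptake else q


def fermentation_metrics(
    fluxes: FluxRecord, threshold: float = MODE_RATIO_THRESHOLD
) -> FermentationMetrics:
    """Lactate:acetate flux ratio and fermentation-mode label.

    Ratio >= ``threshold`` is labelled "homolactic-dominant", below it
    "mixed-acid-shifted". Zero acetate flux yields an infinite ratio
    (homolactic-dominant).
    """
    q_lac = fluxes.q.get("lactate", 0.0)
    q_ace = fluxes.q.get("acetate", 0.0)
    if q_ace < 0 or q_lac < 0:
        raise ChemostatError("product fluxes must be >= 0")
    if q_ace == 0:
        return FermentationMetrics(ratio=math.inf, mode="homolactic-dominant")
    ratio = q_lac / q_ace
    mode = "homolactic-dominant" if ratio >= threshold else "mixed-acid-shifted"
    return FermentationMetrics(ratio=ratio, mode=mode)


@dataclass(frozen=True)
class FermentationStoichiometry:
    """Per-glucose product counts (mol/mol) of an anaerobic fermentation
    mode routing pyruvate through lactate dehydrogenase, pyruvate
    formate-lyase (acetate / ethanol branches) or direct excretion.
    """

    lactate: float = 0.0
    acetate: float = 0.0
    ethanol: float = 0.0
    formate: float = 0.0
    pyruvate_excreted: float = 0.0

    def __post_init__(self) -> None:
        for name in ("lactate", "acetate", "ethanol", "formate",
                     "pyruvate_excreted"):
            if getattr(self, name) < 0:
                raise ChemostatError(f"{name} count must be >= 0")

    @property
    def pyruvate_total(self) -> float:
        return (self.lactate + self.acetate + self.ethanol
                + self.pyruvate_excreted)

    @property
    def nadh_balance(self) -> float:
        """NADH produced minus consumed per glucose.

        Glycolysis makes one NADH per pyruvate; lactate reoxidizes one,
        ethanol two (acetaldehyde + alcohol dehydrogenase); acetate and
        excreted pyruvate none.
        """
        produced = self.pyruvate_total
        consumed = self.lactate + 2.0 * self.ethanol
        return produced - consumed

    @property
    def carbon_balance(self) -> float:
        """Product carbon per glucose (pyruvate-derived C3/C2 skeletons
        plus formate); 6 for a closed anaerobic mode."""
        return (3.0 * self.lactate + 2.0 * self.acetate + 2.0 * self.ethanol
                + 1.0 * self.formate + 3.0 * self.pyruvate_excreted)

    @property
    def atp_per_glucose(self) -> float:
        """Substrate-level phosphorylation: 2 glycolytic ATP per glucose
        plus one acetate-kinase ATP per acetate."""
        return 2.0 + self.acetate


HOMOLACTIC = FermentationStoichiometry(lactate=2.0)
MIXED_ACID = FermentationStoichiometry(acetate=1.0, ethanol=1.0, formate=2.0)


def atp_yield(stoich: FermentationStoichiometry, tol: float = 1e-9) -> float:
    """Validated ATP per glucose for a redox-closed fermentation mode.

    Rejects stoichiometries whose NADH balance is nonzero (reports the
    surplus/deficit), whose pyruvate pool does not account for one full
    glucose, or whose formate does not match the formate-lyase flux.
    """
    bal = stoich.nadh_balance
    if abs(bal) > tol:
        word = "surplus" if bal > 0 else "deficit"
        raise ChemostatError(
            f"redox-imbalanced stoichiometry: NADH {word} of {abs(bal):g} "
            "per glucose"
        )
    if abs(stoich.pyruvate_total - 2.0) > tol:
        raise ChemostatError(
            f"pyruvate pool is {stoich.pyruvate_total:g} per glucose, "
            "expected 2 (one full glucose through glycolysis)"
        )
    if abs(stoich.formate - (stoich.acetate + stoich.ethanol)) > tol:
        raise ChemostatError(
            "formate must equal acetate + ethanol (formate-lyase route)"
        )
    return stoich.atp_per_glucose


def atp_percent_increase(
    reference: FermentationStoichiometry, alternative: FermentationStoichiometry
) -> float:
    """Percent ATP-yield increase of ``alternative`` over ``reference``."""
    a = atp_yield(reference)
    b = atp_yield(alternative)
    return 100.0 * (b - a) / a


def mutation_rate(
    snp_count: int,
    genome_length: float = DEFAULT_GENOME_LENGTH,
    generations: float = 309.0,
) -> float:
    """Per-bp per-generation mutation rate: snp_count/(genome_length*generations)."""
    if snp_count < 0:
        raise ChemostatError(f"snp_count must be >= 0, got {snp_count}")
    if not genome_length > 0:
        raise ChemostatError(f"genome_length must be > 0, got {genome_length}")
    if not generations > 0:
        raise ChemostatError(f"generations must be > 0, got {generations}")
    return snp_count / (genome_length * generations)


@dataclass(frozen=True)
class UptakeFit:
    """Michaelis-Menten fit v = Vmax*S/(Km+S)."""

    Vmax: float
    Km: float
    Vmax_se: float
    Km_se: float
    Vmax_ci95: tuple[float, float]
    Km_ci95: tuple[float, float]
    covariance: np.ndarray = field(repr=False, default=None)

    def predict(self, S) -> np.ndarray:
        S = np.asarray(S, dtype=float)
        return self.Vmax * S / (self.Km + S)


def fit_uptake_kinetics(
    S: Sequence[float], v: Sequence[float], seed: int | None = None,
    error_model: str = "relative",
) -> UptakeFit:
    """Nonlinear least squares of the Michaelis-Menten uptake curve.

    Deterministic given the data (``seed`` is accepted for interface
    symmetry with the generators but unused). Initialization:
    Vmax0 = max(v), Km0 = median(S). 95% CIs are t-based on n-2 dof.
    ``error_model="relative"`` (default) weights residuals by 1/v for
    proportional measurement error; "constant" fits unweighted.
    """
    S = np.asarray(S, dtype=float)
    v = np.asarray(v, dtype=float)
    if S.shape != v.shape:
        raise ChemostatError("S and v length mismatch")
    if np.any(S <= 0):
        raise ChemostatError("concentrations must be > 0")
    if np.unique(S).size < 3:
        raise ChemostatError("need >= 3 distinct concentrations")
    if error_model not in ("relative", "constant"):
        raise ChemostatError(f"unknown error model {error_model!r}")

    def mm(s, vmax, km):
        return vmax * s / (km + s)

    p0 = (float(np.max(v)), float(np.median(S)))
    kwargs = {}
    if error_model == "relative" and np.all(v > 0):
        kwargs["sigma"] = v
        kwargs["absolute_sigma"] = False
    popt, pcov = curve_fit(
        mm, S, v, p0=p0, bounds=([0.0, 0.0], [np.inf, np.inf]),
        maxfev=10000, **kwargs
    )
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    dof = max(S.size - 2, 1)
    tcrit = float(stats.t.ppf(0.975, dof))
    return UptakeFit(
        Vmax=float(popt[0]),
        Km=float(popt[1]),
        Vmax_se=float(se[0]),
        Km_se=float(se[1]),
        Vmax_ci95=(float(popt[0] - tcrit * se[0]), float(popt[0] + tcrit * se[0])),
        Km_ci95=(float(popt[1] - tcrit * se[1]), float(popt[1] + tcrit * se[1])),
        covariance=pcov,
    )


_VALID_BASES = set("ACGT")


@dataclass(frozen=True)
class SNPAnnotation:
    ref_aa: str
    alt_aa: str
    synonymous: bool


@dataclass(frozen=True)
class SNPRecord:
    """A coding SNP with its codon-level consequence (1-based genome
    coordinate on the reference assembly)."""

    position: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    synonymous: bool
    locus: str = ""

    @classmethod
    def from_codons(
        cls, position: int, ref_codon: str, alt_codon: str, locus: str = ""
    ) -> "SNPRecord":
        ann = annotate_snp(ref_codon, alt_codon)
        return cls(
            position=position, ref_codon=ref_codon.upper(),
            alt_codon=alt_codon.upper(), ref_aa=ann.ref_aa,
            alt_aa=ann.alt_aa, synonymous=ann.synonymous, locus=locus,
        )


def _check_codon(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or not set(codon) <= _VALID_BASES:
        raise ChemostatError(f"invalid codon {codon!r}")
    return codon


def annotate_snp(ref_codon: str, alt_codon: str) -> SNPAnnotation:
    """Standard-genetic-code translation of a codon substitution."""
    ref_codon = _check_codon(ref_codon)
    alt_codon = _check_codon(alt_codon)
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return SNPAnnotation(
        ref_aa=ref_aa, alt_aa=alt_aa, synonymous=(ref_aa == alt_aa)
    )
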