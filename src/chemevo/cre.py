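"""Catabolite-responsive-element (cre) motif analysis.

Degenerate-consensus scanning on both strands, mismatch scoring,
position-frequency matrices with information content, and key-position
classification of candidate operator sites.

Coordinates are 0-based half-open internally; key motif positions (C7,
G8, T10, C13) follow the 1-based convention used in reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chemostat import ChemostatError

__all__ = [
    "IUPAC",
    "DEFAULT_CONSENSUS",
    "Consensus",
    "PFMatrix",
    "SiteHit",
    "SiteClass",
    "match_consensus",
    "scan",
    "build_pfm",
    "classify_site",
    "hits_to_frame",
    "write_hits_bed",
    "reverse_complement",
]

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"),
    "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Consensus:
    """An IUPAC degenerate consensus pattern."""

    pattern: str = "TGNNANCGNTTNCA"

    def __post_init__(self) -> None:
        pattern = self.pattern.upper()
        if len(pattern) < 1:
            raise ChemostatError("consensus must have length >= 1")
        bad = set(pattern) - set(IUPAC)
        if bad:
            raise ChemostatError(f"invalid IUPAC characters: {sorted(bad)}")
        object.__setattr__(self, "pattern", pattern)

    def __len__(self) -> int:
        return len(self.pattern)

    def allowed_matrix(self) -> np.ndarray:
        """Boolean (4, L) table: allowed[base, position]."""
        L = len(self.pattern)
        allowed = np.zeros((4, L), dtype=bool)
        for j, ch in enumerate(self.pattern):
            for b in IUPAC[ch]:
                allowed[_BASE_INDEX[b], j] = True
        return allowed

    def reverse_complement(self) -> "Consensus":
        return Consensus(reverse_complement(self.pattern))


DEFAULT_CONSENSUS = Consensus()


def _encode(seq: str) -> np.ndarray:
    """Map sequence to base indices; non-ACGT characters get index 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def match_consensus(site: str, consensus: Consensus = DEFAULT_CONSENSUS) -> int:
    """Mismatch count of ``site`` against the consensus: positions where
    the site base is outside the IUPAC set (N matches everything)."""
    site = site.upper()
    if len(site) != len(consensus):
        raise ChemostatError(
            f"site length {len(site)} != consensus length {len(consensus)}"
        )
    bad = set(site) - set(_BASES)
    if bad:
        raise ChemostatError(f"site contains non-ACGT characters: {sorted(bad)}")
    return int(sum(
        1 for b, ch in zip(site, consensus.pattern) if b not in IUPAC[ch]
    ))


@dataclass(frozen=True)
class SiteHit:
    """A motif match: 0-based half-open ``[start, start+L)`` on the
    forward coordinate system; ``site_seq`` is given in motif
    orientation (reverse-complemented for '-' strand hits)."""

    seq_id: str
    start: int
    strand: str
    mismatches: int
    site_seq: str

    @property
    def end(self) -> int:
        return self.start + len(self.site_seq)


def _normalize_records(
    sequences: Iterable,
) -> list[tuple[str, str]]:
    records = []
    for rec in sequences:
        if isinstance(rec, tuple):
            records.append((str(rec[0]), str(rec[1])))
        else:  # Bio.SeqRecord.SeqRecord or similar
            records.append((str(rec.id), str(rec.seq)))
    return records


def _window_mismatches(codes: np.ndarray, allowed: np.ndarray) -> np.ndarray:
    """Mismatch counts of every window (vectorized sliding window)."""
    L = allowed.shape[1]
    n_win = codes.size - L + 1
    if n_win <= 0:
        return np.empty(0, dtype=int)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    # pad the allowed table so non-ACGT codes (index 4) never match
    padded = np.vstack([allowed, np.zeros((1, L), dtype=bool)])
    ok = padded[win, np.arange(L)]
    return L - ok.sum(axis=1)


def scan(
    sequences: Iterable,
    consensus: Consensus = DEFAULT_CONSENSUS,
    max_mismatch: int = 0,
) -> list[SiteHit]:
    """Report every window on both strands with at most ``max_mismatch``
    mismatches to the consensus, sorted by (seq_id, start, strand).

    ``sequences`` may be Bio SeqRecords or (id, sequence) tuples. An
    empty input or sequences shorter than the motif yield no hits.
    """
    if max_mismatch < 0:
        raise ChemostatError(f"max_mismatch must be >= 0, got {max_mismatch}")
    L = len(consensus)
    allowed_f = consensus.allowed_matrix()
    allowed_r = consensus.reverse_complement().allowed_matrix()
    hits: list[SiteHit] = []
    for seq_id, seq in _normalize_records(sequences):
        codes = _encode(seq)
        for strand, allowed in (("+", allowed_f), ("-", allowed_r)):
            mism = _window_mismatches(codes, allowed)
            for start in np.nonzero(mism <= max_mismatch)[0]:
                window = seq[start:start + L].upper()
                site_seq = window if strand == "+" else reverse_complement(window)
                hits.append(SiteHit(
                    seq_id=seq_id, start=int(start), strand=strand,
                    mismatches=int(mism[start]), site_seq=site_seq,
                ))
    hits.sort(key=lambda h: (h.seq_id, h.start, h.strand))
    return hits


def hits_to_frame(hits: Sequence[SiteHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "seq_id": h.seq_id, "start": h.start, "end": h.end,
                "strand": h.strand, "mismatches": h.mismatches,
                "site_seq": h.site_seq,
            }
            for h in hits
        ],
        columns=["seq_id", "start", "end", "strand", "mismatches", "site_seq"],
    )


def write_hits_bed(hits: Sequence[SiteHit], path, header_comment=None) -> None:
    """BED-like tab-delimited output (0-based half-open)."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        hits_to_frame(hits).to_csv(fh, sep="\t", index=False)


@dataclass
class PFMatrix:
    """Position frequency matrix over A,C,G,T (rows) with pseudocounts."""

    counts: np.ndarray
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ChemostatError("counts must be a 4 x L matrix")
        if np.any(self.counts < 0):
            raise ChemostatError("counts must be non-negative")
        if self.pseudocount < 0:
            raise ChemostatError("pseudocount must be >= 0")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def frequencies(self) -> np.ndarray:
        c = self.counts + self.pseudocount
        return c / c.sum(axis=0, keepdims=True)

    def info_content(self) -> np.ndarray:
        """Per-position information content in bits against a uniform
        background: 2 + sum_b p log2 p."""
        p = self.frequencies()
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        return np.clip(2.0 + plogp.sum(axis=0), 0.0, 2.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(_BASES))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def build_pfm(
    aligned_sites: Sequence[str], pseudocount: float = 0.5
) -> PFMatrix:
    """Per-position base counts of equal-length aligned sites."""
    sites = [s.upper() for s in aligned_sites]
    if not sites:
        raise ChemostatError("need at least one site")
    L = len(sites[0])
    if any(len(s) != L for s in sites):
        raise ChemostatError("aligned sites must all have equal length")
    counts = np.zeros((4, L), dtype=float)
    for s in sites:
        bad = set(s) - set(_BASES)
        if bad:
            raise ChemostatError(f"non-ACGT characters in site: {sorted(bad)}")
        for j, b in enumerate(s):
            counts[_BASE_INDEX[b], j] += 1.0
    return PFMatrix(counts=counts, pseudocount=pseudocount)


@dataclass(frozen=True)
class SiteClass:
    """Key-position report of a 14-mer candidate site (1-based motif
    positions)."""

    label: str
    has_C7: bool
    has_G8: bool
    has_C13: bool
    has_T10: bool

    @property
    def t10_atypical(self) -> bool:
        return not self.has_T10


def classify_site(site: str) -> SiteClass:
    """Classify a 14-mer by its key positions: "consensus-like" when
    C7, G8 and C13 are all present, "deviant" otherwise; absence of T10
    is flagged atypical."""
    site = site.upper()
    if len(site) != 14:
        raise ChemostatError(f"site must be a 14-mer, got length {len(site)}")
    bad = set(site) - set(_BASES)
    if bad:
        raise ChemostatError(f"site contains non-ACGT characters: {sorted(bad)}")
    has_C7 = site[6] == "C"
    has_G8 = site[7] == "G"
    has_C13 = site[12] == "C"
    has_T10 = site[9] == "T"
    label = "consensus-like" if (has_C7 and has_G8 and has_C13) else "deviant"
    return SiteClass(
        label=label, has_C7=has_C7, has_G8=has_G8,
        has_C13=has_C13, has_T10=has_T10,
    )
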