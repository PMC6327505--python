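"""File formats, configuration and report helpers shared by the CLI.

CSV dialect: comma-separated, UTF-8, mandatory header row, '.' decimal
separator; an optional leading '#' comment line carries provenance
(version, seed, config hash). FASTA via Biopython; BED-like motif hits
are tab-delimited 0-based half-open.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .chemostat import ChemostatConfig, ChemostatError, StrainParams, Trajectory
from .competition import EmergenceSpec, FractionSeries

__all__ = [
    "load_config",
    "config_hash",
    "header_comment",
    "strain_from_config",
    "chemostat_from_config",
    "emergence_from_config",
    "read_fractions",
    "read_trajectory",
    "read_fasta",
    "write_fasta",
    "read_flux_table",
    "write_report",
    "write_frame",
]


def load_config(path) -> dict:
    """YAML key-value run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ChemostatError(f"config file {path} is not a mapping")
    return dict(cfg)


def config_hash(cfg: Mapping) -> str:
    """Short stable hash of a configuration mapping."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha1(canon.encode()).hexdigest()[:12]


def header_comment(seed=None, cfg: Mapping | None = None, **extra) -> str:
    parts = [f"chemevo v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if cfg is not None:
        parts.append(f"config={config_hash(cfg)}")
    parts.extend(f"{k}={v}" for k, v in extra.items())
    return " ".join(parts)


def strain_from_config(cfg: Mapping, key: str) -> StrainParams:
    try:
        sub = cfg[key]
        return StrainParams(
            name=str(sub.get("name", key)),
            mu_max=float(sub["mu_max"]),
            K_M=float(sub["K_M"]),
            biomass_yield=float(sub.get("yield", 1.0)),
        )
    except KeyError as exc:
        raise ChemostatError(f"config missing {key}.{exc.args[0]}") from None


def chemostat_from_config(cfg: Mapping) -> ChemostatConfig:
    try:
        sub = cfg["chemostat"]
        return ChemostatConfig(
            D=float(sub["D"]),
            S_in=float(sub["S_in"]),
            V=float(sub.get("V", 60.0)),
        )
    except KeyError as exc:
        raise ChemostatError(f"config missing chemostat.{exc.args[0]}") from None


def emergence_from_config(cfg: Mapping) -> EmergenceSpec:
    sub = cfg.get("emergence", {})
    return EmergenceSpec(
        t_emerge=float(sub.get("t_emerge", 0.0)),
        amount=float(sub.get("amount", 1e-6)),
        mode=str(sub.get("mode", "frequency")),
        time_unit=str(sub.get("time_unit", "hours")),
    )


def read_fractions(path) -> FractionSeries:
    return FractionSeries.from_csv(path)


def read_trajectory(path) -> Trajectory:
    return Trajectory.from_csv(path)


def read_fasta(path) -> list:
    return list(SeqIO.parse(str(path), "fasta"))


def write_fasta(records, path) -> None:
    SeqIO.write(records, str(path), "fasta")


def read_flux_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    for col in ("metabolite", "c_in_mM", "c_out_mM"):
        if col not in df.columns:
            raise ChemostatError(f"flux table missing column {col!r}")
    return df


def write_report(path, mapping: Mapping, comment: str | None = None) -> None:
    """Flat key=value report file."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        for k, v in mapping.items():
            fh.write(f"{k}={v}\n")


def write_frame(df: pd.DataFrame, path, comment: str | None = None,
                sep: str = ",") -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, index=False, sep=sep)
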