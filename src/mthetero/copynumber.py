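"""Mitochondrial copy number from WGS coverage, and MCN-normalized mutation rates.

A diploid nucleus carries two copies of each chromosome, so the per-cell
mitochondrial genome count is estimated as twice the ratio of mean
mitochondrial to mean nuclear sequencing coverage.  Mutation rates are
normalized by MCN because a cell with more mtDNA copies presents a larger
mutational target.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

CALLABLE_BASES = 16565  # 16,569 minus the 4 excluded positions


@dataclass(frozen=True)
class CoverageRecord:
    sample_id: str
    mito_coverage: float    # mean reads per base over chrM
    nuclear_coverage: float  # mean reads per base over the nuclear genome

    def __post_init__(self) -> None:
        if self.mito_coverage < 0 or self.nuclear_coverage < 0:
            raise ValueError(f"{self.sample_id}: negative coverage")


def mcn(record: CoverageRecord) -> float:
    """Mitochondrial copy number per cell: 2 × mito / nuclear coverage."""
    if record.nuclear_coverage == 0:
        raise ValueError(f"{record.sample_id}: nuclear coverage is zero")
    return 2.0 * record.mito_coverage / record.nuclear_coverage


def mutation_rate_per_mbp(n_mtsnvs: int, mcn_value: float,
                          callable_bases: int = CALLABLE_BASES) -> float:
    """Somatic mtSNV rate per megabase of mtDNA, normalized by copy number.

    ``n / (MCN × callable_bases) × 1e6``; the ×1e6 rescaling makes the unit
    literally per-Mbp.  Use :func:`mutation_rate_per_base` for the raw rate.
    """
    return mutation_rate_per_base(n_mtsnvs, mcn_value, callable_bases) * 1e6


def mutation_rate_per_base(n_mtsnvs: int, mcn_value: float,
                           callable_bases: int = CALLABLE_BASES) -> float:
    if n_mtsnvs < 0:
        raise ValueError("negative mtSNV count")
    if mcn_value <= 0:
        raise ValueError("MCN must be positive")
    return n_mtsnvs / (mcn_value * callable_bases)


def per_locus_frequency(n_mutations_in_locus: int, locus_length_kbp: float,
                        mcn_value: float) -> float:
    """Per-locus mutation frequency: n / (locus length in kbp × MCN)."""
    if locus_length_kbp <= 0:
        raise ValueError("locus length must be positive")
    if mcn_value <= 0:
        raise ValueError("MCN must be positive")
    if n_mutations_in_locus < 0:
        raise ValueError("negative mutation count")
    return n_mutations_in_locus / (locus_length_kbp * mcn_value)


def read_coverage_tsv(path: str | Path) -> list[CoverageRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "mito_coverage", "nuclear_coverage"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return [CoverageRecord(str(r.sample), float(r.mito_coverage),
                           float(r.nuclear_coverage)) for r in df.itertuples()]


def mcn_table(records) -> pd.DataFrame:
    """Per-sample MCN as a DataFrame with columns sample, mcn."""
    return pd.DataFrame([(r.sample_id, mcn(r)) for r in records],
                        columns=["sample", "mcn"])
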