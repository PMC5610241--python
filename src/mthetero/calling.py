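"""Somatic mitochondrial SNV calling from paired tumor/normal heteroplasmy tables.

A variant is a somatic mtSNV when the absolute difference in heteroplasmy
fraction (ΔHF) between the purity-adjusted tumor sample and the paired normal
is at least 0.20, the position is not one of the four excluded sites, and both
samples have ≥100× read depth at the position.  The purity adjustment inverts
cellularity contamination of the macro-dissected tumor specimen:

    HF_tumor,adjusted = (HF_tumor − (1 − cellularity) · HF_normal) / cellularity

with values clamped into [0, 1] before ΔHF is taken.  Heteroplasmy fractions
are alt-allele read fractions; ΔHF is computed per alternate allele, so a
normal-heteroplasmic site fixing in the tumor is representable.

Coding consequences use the vertebrate mitochondrial genetic code (NCBI
translation table 2): AGA/AGG are stops, ATA codes Met.  Light-strand genes
(ND6) are read on the reverse complement.  Genes whose length is not a
multiple of three end in an incomplete stop codon completed by
polyadenylation; such terminal codons are treated as stops, so a substitution
destroying one is classified stop_lost.
"""
from __future__ import annotations

import operator
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .reference import MitoAnnotation, load_annotation

MITO_TABLE = unambiguous_dna_by_id[2]
_STOPS = set(MITO_TABLE.stop_codons)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

CONSEQUENCES = ("synonymous", "missense", "stop_gained", "stop_lost",
                "tRNA", "rRNA", "noncoding")
#: ordering used when a position lies in overlapping protein genes
_SEVERITY = {"stop_gained": 0, "stop_lost": 1, "missense": 2, "synonymous": 3}

DEFAULT_DELTA_HF = 0.20
DEFAULT_MIN_DEPTH = 100


@dataclass(frozen=True)
class HeteroplasmyRecord:
    """Observed non-reference allele at one position in one sample."""

    position: int
    ref_allele: str
    alt_allele: str
    allele_fraction: float
    depth: int

    def __post_init__(self) -> None:
        if not 1 <= self.position <= 16569:
            raise ValueError(f"position {self.position} outside [1, 16569]")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref == alt ({self.ref_allele}) at {self.position}")
        if self.depth < 0:
            raise ValueError("negative depth")
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise ValueError(f"allele fraction {self.allele_fraction} outside [0, 1]")


@dataclass(frozen=True)
class MtSNV:
    """A called somatic mitochondrial single-nucleotide variant."""

    position: int
    ref_allele: str
    alt_allele: str
    tumor_hf_raw: float
    tumor_hf_adjusted: float
    normal_hf: float
    delta_hf: float
    regions: frozenset[str]
    consequence: str
    protein_change: str | None = None


def adjust_tumor_hf(tumor_hf: float, normal_hf: float,
                    cellularity: float | None = 1.0,
                    clamp: bool = True) -> float:
    """Purity-adjust a tumor heteroplasmy fraction against its paired normal.

    ``(tumor_hf − (1 − cellularity) · normal_hf) / cellularity``, clamped into
    [0, 1].  ``cellularity=None`` means unknown and is treated as 1.0.
    """
    if cellularity is None:
        cellularity = 1.0
    if not 0.0 <= tumor_hf <= 1.0 or not 0.0 <= normal_hf <= 1.0:
        raise ValueError("heteroplasmy fractions must be in [0, 1]")
    if not 0.0 < cellularity <= 1.0:
        raise ValueError(f"cellularity {cellularity} outside (0, 1]")
    adjusted = (tumor_hf - (1.0 - cellularity) * normal_hf) / cellularity
    if clamp:
        adjusted = min(1.0, max(0.0, adjusted))
    return adjusted


def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _codon_at(annotation: MitoAnnotation, gene, position: int,
              alt: str | None = None) -> tuple[int, int, str]:
    """(codon_number_1based, offset_in_codon, codon) for *position* in *gene*.

    The codon is in reading orientation; an incomplete terminal codon is
    polyadenylation-completed.  With *alt*, the codon carries the substituted
    base.
    """
    seq = annotation.reference_sequence
    if gene.strand == "heavy":
        offset = position - gene.start
    else:
        offset = gene.end - position
    codon_i = offset // 3
    in_codon = offset % 3
    bases = []
    for k in range(3):
        if gene.strand == "heavy":
            p = gene.start + 3 * codon_i + k
            inside = p <= gene.end
            b = seq[p - 1] if inside else "A"
        else:
            p = gene.end - 3 * codon_i - k
            inside = p >= gene.start
            b = _COMP[seq[p - 1]] if inside else "A"
        if alt is not None and k == in_codon:
            b = alt if gene.strand == "heavy" else _COMP[alt]
        bases.append(b)
    return codon_i + 1, in_codon, "".join(bases)


def _translate(codon: str) -> str:
    if codon in _STOPS:
        return "*"
    return MITO_TABLE.forward_table[codon]


def annotate_consequence(position: int, ref_allele: str, alt_allele: str,
                         annotation: MitoAnnotation,
                         ) -> tuple[str, str | None]:
    """Classify a substitution; returns (consequence, protein_change or None).

    Protein changes are 1-based from the gene's initiator methionine, e.g.
    ``E214K``.  At positions inside overlapping genes the most severe
    consequence is reported.
    """
    for allele in (ref_allele, alt_allele):
        if allele not in "ACGT" or len(allele) != 1:
            raise ValueError(f"allele {allele!r} not a single base in ACGT")
    if position in annotation.excluded_positions:
        raise ValueError(f"position {position} is excluded from analysis")
    if annotation.ref_base(position) != ref_allele:
        raise ValueError(
            f"ref allele {ref_allele} does not match reference "
            f"{annotation.ref_base(position)} at {position}")

    hits = annotation.regions_of(position)
    coding = [annotation.region(n) for n in hits
              if annotation.region(n).region_class == "protein_coding"]
    if coding:
        results = []
        for gene in coding:
            codon_n, _, ref_codon = _codon_at(annotation, gene, position)
            _, _, alt_codon = _codon_at(annotation, gene, position, alt_allele)
            ref_aa, alt_aa = _translate(ref_codon), _translate(alt_codon)
            if ref_aa == alt_aa:
                csq = "synonymous"
            elif alt_aa == "*":
                csq = "stop_gained"
            elif ref_aa == "*":
                csq = "stop_lost"
            else:
                csq = "missense"
            results.append((csq, f"{ref_aa}{codon_n}{alt_aa}"))
        results.sort(key=lambda r: _SEVERITY[r[0]])
        return results[0]
    classes = {annotation.region(n).region_class for n in hits}
    if "tRNA" in classes:
        return "tRNA", None
    if "rRNA" in classes:
        return "rRNA", None
    return "noncoding", None


def call_mtsnvs(tumor_records: Sequence[HeteroplasmyRecord],
                normal_records: Sequence[HeteroplasmyRecord],
                cellularity: float | None = 1.0,
                annotation: MitoAnnotation | None = None,
                delta_hf_threshold: float = DEFAULT_DELTA_HF,
                min_depth: int = DEFAULT_MIN_DEPTH,
                comparator: str = ">=") -> list[MtSNV]:
    """Call somatic mtSNVs from paired tumor/normal heteroplasmy tables.

    ΔHF is evaluated per (position, alt allele); an allele absent from the
    normal table has normal HF 0, provided the normal covers the position.
    The depth filter applies to both samples: an unreliable normal corrupts
    ΔHF just as an unreliable tumor does.  Positions the normal table does
    not cover at all are uncallable under the paired design and are skipped.

    *comparator* selects ``>=`` ("at least 0.20") or ``>`` at the threshold
    boundary.
    """
    if normal_records is None:
        raise ValueError("paired design is mandatory: normal table missing")
    if not 0.0 < delta_hf_threshold < 1.0:
        raise ValueError("delta_hf_threshold must be in (0, 1)")
    cmp = {">=": operator.ge, ">": operator.gt}[comparator]
    if annotation is None:
        annotation = load_annotation()

    normal_by_allele = {(r.position, r.alt_allele): r for r in normal_records}
    normal_depth = {r.position: r.depth for r in normal_records}

    calls = []
    for rec in sorted(tumor_records, key=lambda r: (r.position, r.alt_allele)):
        if rec.position in annotation.excluded_positions:
            continue
        if rec.position not in normal_depth:
            continue
        if rec.depth < min_depth or normal_depth[rec.position] < min_depth:
            continue
        nrec = normal_by_allele.get((rec.position, rec.alt_allele))
        normal_hf = nrec.allele_fraction if nrec is not None else 0.0
        adjusted = adjust_tumor_hf(rec.allele_fraction, normal_hf, cellularity)
        delta = abs(adjusted - normal_hf)
        if not cmp(delta, delta_hf_threshold):
            continue
        csq, pchange = annotate_consequence(rec.position, rec.ref_allele,
                                            rec.alt_allele, annotation)
        calls.append(MtSNV(
            position=rec.position, ref_allele=rec.ref_allele,
            alt_allele=rec.alt_allele, tumor_hf_raw=rec.allele_fraction,
            tumor_hf_adjusted=adjusted, normal_hf=normal_hf, delta_hf=delta,
            regions=frozenset(annotation.regions_of(rec.position)),
            consequence=csq, protein_change=pchange))
    return calls


# ---------------------------------------------------------------------------
# I/O

HETEROPLASMY_COLUMNS = ["position", "ref", "alt", "allele_fraction", "depth"]


def records_from_frame(df: pd.DataFrame) -> list[HeteroplasmyRecord]:
    missing = set(HETEROPLASMY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)}")
    return [HeteroplasmyRecord(int(r.position), r.ref, r.alt,
                               float(r.allele_fraction), int(r.depth))
            for r in df.itertuples()]


def read_heteroplasmy_tsv(path: str | Path) -> list[HeteroplasmyRecord]:
    return records_from_frame(pd.read_csv(path, sep="\t"))


def write_heteroplasmy_tsv(records: Iterable[HeteroplasmyRecord],
                           path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.position, r.ref_allele, r.alt_allele, r.allele_fraction, r.depth)
         for r in records], columns=HETEROPLASMY_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def calls_to_frame(calls: Sequence[MtSNV]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.position, c.ref_allele, c.alt_allele, c.tumor_hf_raw,
          c.tumor_hf_adjusted, c.normal_hf, c.delta_hf,
          ",".join(sorted(c.regions)), c.consequence, c.protein_change or ".")
         for c in calls],
        columns=["position", "ref", "alt", "tumor_hf_raw", "tumor_hf_adjusted",
                 "normal_hf", "delta_hf", "regions", "consequence",
                 "protein_change"])


def write_calls_tsv(calls: Sequence[MtSNV], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | Path) -> list[MtSNV]:
    df = pd.read_csv(path, sep="\t", na_filter=False)
    out = []
    for r in df.itertuples():
        out.append(MtSNV(
            position=int(r.position), ref_allele=r.ref, alt_allele=r.alt,
            tumor_hf_raw=float(r.tumor_hf_raw),
            tumor_hf_adjusted=float(r.tumor_hf_adjusted),
            normal_hf=float(r.normal_hf), delta_hf=float(r.delta_hf),
            regions=frozenset(str(r.regions).split(",")) if r.regions else frozenset(),
            consequence=r.consequence,
            protein_change=None if r.protein_change == "." else r.protein_change))
    return out


_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chrM,length=16569>
##INFO=<ID=DHF,Number=1,Type=Float,Description="Absolute difference between adjusted tumor and normal heteroplasmy fraction">
##INFO=<ID=THF_ADJ,Number=1,Type=Float,Description="Purity-adjusted tumor heteroplasmy fraction">
##INFO=<ID=NHF,Number=1,Type=Float,Description="Normal heteroplasmy fraction">
##INFO=<ID=REGIONS,Number=.,Type=String,Description="Annotated mitochondrial regions containing the site">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Coding consequence (vertebrate mitochondrial code)">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_calls_vcf(calls: Sequence[MtSNV], path: str | Path) -> None:
    """Write calls as a minimal sorted single-sample-pair VCF 4.2."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in sorted(calls, key=lambda c: (c.position, c.alt_allele)):
            csq = c.consequence
            if c.protein_change:
                csq += f"|{c.protein_change}"
            info = (f"DHF={c.delta_hf:.4f};THF_ADJ={c.tumor_hf_adjusted:.4f};"
                    f"NHF={c.normal_hf:.4f};"
                    f"REGIONS={','.join(sorted(c.regions)) or '.'};CSQ={csq}")
            fh.write(f"chrM\t{c.position}\t.\t{c.ref_allele}\t{c.alt_allele}"
                     f"\t.\tPASS\t{info}\n")
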