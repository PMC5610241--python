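"""Mitochondrial genome annotation: regions, excluded sites, reference sequence.

The human mitochondrial genome is a 16,569 bp circle numbered in the rCRS
convention (1-based, both-ends inclusive).  The noncoding control region wraps
the origin (16,024–576) and contains the hypervariable segments HV1
(16,024–16,383) and HV2 (57–372), the heavy-strand replication origin region
OHR (110–441) and three conserved sequence blocks CSB1–3.  Four positions
(310, 523, 524, 3107) are prone to misalignment — 3107 is an historical ``N``
placeholder — and are excluded from variant calling, leaving 16,565 callable
bases.

The packaged default annotation carries the standard gene map (13
protein-coding genes, 2 rRNAs, 22 tRNAs, the control region and its
subregions).  The packaged reference FASTA is a SYNTHETIC sequence on rCRS
coordinates (see ``data/synthetic_rcrs_like.fasta``); supply a real rCRS FASTA
via :func:`load_annotation` to annotate real data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

MT_LENGTH = 16569
DEFAULT_EXCLUDED = frozenset({310, 523, 524, 3107})

REGION_CLASSES = ("protein_coding", "rRNA", "tRNA", "control_region",
                  "control_subregion")

#: subregion -> parent region (nesting used by the feature matrix)
SUBREGION_PARENTS = {
    "HV1": "control_region",
    "HV2": "control_region",
    "OHR": "control_region",
    "CSB1": "control_region",
    "CSB2": "control_region",
    "CSB3": "control_region",
}

PROTEIN_GENES = ("ND1", "ND2", "CO1", "CO2", "ATP8", "ATP6", "CO3", "ND3",
                 "ND4L", "ND4", "ND5", "ND6", "CYB")
RRNA_GENES = ("RNR1", "RNR2")


@dataclass(frozen=True)
class MitoRegion:
    """One annotated span of the circular mitochondrial genome."""

    name: str
    region_class: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive; end < start means the span wraps 16569/1
    strand: str = "heavy"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= MT_LENGTH and 1 <= self.end <= MT_LENGTH):
            raise ValueError(f"{self.name}: coordinates outside [1, {MT_LENGTH}]")
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"{self.name}: unknown region class {self.region_class!r}")
        if self.strand not in ("heavy", "light"):
            raise ValueError(f"{self.name}: strand must be heavy or light")

    @property
    def wraps_origin(self) -> bool:
        return self.end < self.start

    def __contains__(self, position: int) -> bool:
        if self.wraps_origin:
            return position >= self.start or position <= self.end
        return self.start <= position <= self.end

    @property
    def length(self) -> int:
        if self.wraps_origin:
            return (MT_LENGTH - self.start + 1) + self.end
        return self.end - self.start + 1

    def positions(self) -> Iterable[int]:
        if self.wraps_origin:
            yield from range(self.start, MT_LENGTH + 1)
            yield from range(1, self.end + 1)
        else:
            yield from range(self.start, self.end + 1)


@dataclass(frozen=True)
class MitoAnnotation:
    """Validated region map plus reference sequence and excluded sites."""

    regions: tuple[MitoRegion, ...]
    reference_sequence: str
    excluded_positions: frozenset[int] = DEFAULT_EXCLUDED
    reference_length: int = MT_LENGTH
    _by_name: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.reference_sequence) != self.reference_length:
            raise ValueError(
                f"reference sequence length {len(self.reference_sequence)} != "
                f"{self.reference_length}")
        names = [r.name for r in self.regions]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate region names: {sorted(dupes)}")
        object.__setattr__(self, "_by_name", {r.name: r for r in self.regions})

    def region(self, name: str) -> MitoRegion:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def regions_of(self, position: int) -> set[str]:
        return regions_of(position, self)

    @property
    def callable_positions(self) -> int:
        return callable_positions(self)

    def ref_base(self, position: int) -> str:
        if not 1 <= position <= self.reference_length:
            raise ValueError(f"position {position} outside [1, {self.reference_length}]")
        return self.reference_sequence[position - 1]

    def genes(self, region_class: str) -> list[MitoRegion]:
        return [r for r in self.regions if r.region_class == region_class]


def regions_of(position: int, annotation: MitoAnnotation) -> set[str]:
    """Names of every annotated region containing *position* (wrap-aware).

    Subregions are reported alongside their parents: position 300 is in
    OHR, HV2, CSB2 and the control region at once.
    """
    if not 1 <= position <= annotation.reference_length:
        raise ValueError(f"position {position} outside [1, {annotation.reference_length}]")
    return {r.name for r in annotation.regions if position in r}


def callable_positions(annotation: MitoAnnotation) -> int:
    """Number of analyzable bases: reference length minus excluded sites."""
    return annotation.reference_length - len(annotation.excluded_positions)


def _read_fasta(path) -> str:
    rec = next(SeqIO.parse(str(path), "fasta"))
    return str(rec.seq).upper()


def _read_regions(path) -> tuple[MitoRegion, ...]:
    regions = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["name", "class", "start", "end", "strand"]
        if header != expected:
            raise ValueError(f"region table header {header} != {expected}")
        for line in fh:
            if not line.strip():
                continue
            name, cls, start, end, strand = line.rstrip("\n").split("\t")
            regions.append(MitoRegion(name, cls, int(start), int(end), strand))
    return tuple(regions)


def _validate_default_composition(annotation: MitoAnnotation) -> None:
    counts = {c: len(annotation.genes(c)) for c in REGION_CLASSES}
    expected = {"protein_coding": 13, "rRNA": 2, "tRNA": 22,
                "control_region": 1, "control_subregion": 6}
    if counts != expected:
        raise ValueError(f"region composition {counts} != {expected}")
    for name in PROTEIN_GENES + RRNA_GENES + tuple(SUBREGION_PARENTS):
        if name not in annotation:
            raise ValueError(f"missing region {name}")


def load_annotation(annotation_file: str | Path | None = None,
                    fasta_file: str | Path | None = None,
                    excluded_positions: Iterable[int] = DEFAULT_EXCLUDED,
                    ) -> MitoAnnotation:
    """Load a region table (TSV) and reference FASTA into a MitoAnnotation.

    With no arguments, the packaged defaults are used (standard rCRS gene
    map, synthetic reference sequence) and the full 37-gene composition is
    enforced.  Custom files are validated for coordinates, duplicates and
    sequence length only.
    """
    data = resources.files("mthetero") / "data"
    use_defaults = annotation_file is None
    if annotation_file is None:
        annotation_file = data / "regions.tsv"
    if fasta_file is None:
        fasta_file = data / "synthetic_rcrs_like.fasta"
    annotation = MitoAnnotation(
        regions=_read_regions(annotation_file),
        reference_sequence=_read_fasta(fasta_file),
        excluded_positions=frozenset(excluded_positions),
    )
    if use_defaults:
        _validate_default_composition(annotation)
    return annotation
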