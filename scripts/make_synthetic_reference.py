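"""Regenerate the packaged synthetic mitochondrial reference sequence.

The packaged FASTA (``src/mthetero/data/synthetic_rcrs_like.fasta``) is a
SYNTHETIC stand-in for the human mitochondrial reference: it uses the rCRS
coordinate system (16,569 bp, historical ``N`` placeholder at 3107) and the
standard gene map, but the sequence itself is generated.  Constraints honoured:

* every protein-coding gene is a valid ORF under the vertebrate mitochondrial
  genetic code (NCBI table 2): ATG start, no internal stop codons, and a
  terminal stop that is complete (TAA) or polyadenylation-completed (T / TA)
  exactly where the real gene lengths dictate;
* ND6 is encoded on the light strand (its ORF reads on the reverse
  complement), as in the real genome;
* codons that published worked examples pin down are placed faithfully:
  ND1 codon 179 = TGA (G3842A creates a premature stop), codon 214 = GAA
  (G3946A -> E214K), codon 279 = CGA (G4142A -> R279Q); CO1 codon 254 = ATT
  (T6664C -> I254T) and the codon at 5910 = GCC (G5910A -> Ala->Thr).

Run from the repository root:

    python scripts/make_synthetic_reference.py
"""
from __future__ import annotations

import sys
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "src" / "mthetero" / "data" / "synthetic_rcrs_like.fasta"

L = 16569
STOPS = {"TAA", "TAG", "AGA", "AGG"}  # vertebrate mito code
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# name -> (start, end, strand); 1-based inclusive, from the standard rCRS map
GENES = {
    "ND1": (3307, 4262, "H"),
    "ND2": (4470, 5511, "H"),
    "CO1": (5904, 7445, "H"),
    "CO2": (7586, 8269, "H"),
    "ATP8": (8366, 8572, "H"),
    "ATP6": (8527, 9207, "H"),
    "CO3": (9207, 9990, "H"),
    "ND3": (10059, 10404, "H"),
    "ND4L": (10470, 10766, "H"),
    "ND4": (10760, 12137, "H"),
    "ND5": (12337, 14148, "H"),
    "ND6": (14149, 14673, "L"),
    "CYB": (14747, 15887, "H"),
}

# pinned genomic bases (1-based): worked-example codons
PINS: dict[int, str] = {}


def pin(start: int, bases: str) -> None:
    for i, b in enumerate(bases):
        p = start + i
        if p in PINS and PINS[p] != b:
            raise ValueError(f"conflicting pin at {p}: {PINS[p]} vs {b}")
        PINS[p] = b


def pin_gene_ends() -> None:
    for name, (s, e, strand) in GENES.items():
        n = e - s + 1
        if strand == "H":
            pin(s, "ATG")
            rem = n % 3
            if rem == 0:
                if name not in ("ATP6",):  # ATP6 stop pinned jointly with CO3 start
                    pin(e - 2, "TAA")
            elif rem == 1:
                pin(e, "T")
            else:
                pin(e - 1, "TA")
        else:  # light strand: ORF on reverse complement
            # genomic end holds the revcomp of ATG = CAT
            pin(e - 2, "CAT")
            if n % 3 == 0:
                pin(s, "TTA")  # revcomp of TAA
            else:
                raise ValueError("light-strand gene with incomplete stop unsupported")
    # ATP6 (ends 9207) and CO3 (starts 9207) share one base: TAA stop then ATG
    pin(9205, "TA")
    pin(9207, "ATG")


def pin_worked_examples() -> None:
    pin(3841, "TGA")   # ND1 codon 179 (Trp) -> G3842A gives TAA stop
    pin(3946, "GAA")   # ND1 codon 214 (Glu) -> G3946A gives AAA (E214K)
    pin(4141, "CGA")   # ND1 codon 279 (Arg) -> G4142A gives CAA (R279Q)
    pin(6663, "ATT")   # CO1 codon 254 (Ile) -> T6664C gives ACT (I254T)
    pin(5910, "GCC")   # CO1: G5910A gives ACC (Ala->Thr)


def codon_positions(name: str):
    """Yield (codon_index, [genomic positions in reading order]) for internal codons."""
    s, e, strand = GENES[name]
    n = e - s + 1
    ncod = n // 3
    for i in range(ncod):
        if strand == "H":
            posns = [s + 3 * i, s + 3 * i + 1, s + 3 * i + 2]
        else:
            posns = [e - 3 * i, e - 3 * i - 1, e - 3 * i - 2]
        yield i, posns


def read_codon(seq: list[str], posns, strand: str) -> str:
    if strand == "H":
        return "".join(seq[p - 1] for p in posns)
    return "".join(COMP[seq[p - 1]] for p in posns)


def write_codon(seq: list[str], posns, strand: str, codon: str) -> None:
    for p, b in zip(posns, codon):
        seq[p - 1] = b if strand == "H" else COMP[b]


def repair(seq: list[str], rng: np.random.Generator) -> None:
    """Remove internal stop codons without touching pinned bases."""
    for _ in range(200):
        dirty = False
        for name, (s, e, strand) in GENES.items():
            n = e - s + 1
            last = n // 3 - 1 if n % 3 == 0 else n // 3  # index of terminal/stop codon
            for i, posns in codon_positions(name):
                if i == 0 or (n % 3 == 0 and i == last):
                    continue  # start / terminal stop codon
                cod = read_codon(seq, posns, strand)
                if cod not in STOPS:
                    continue
                free = [k for k in range(3) if posns[k] not in PINS]
                if not free:
                    raise ValueError(f"stop codon fully pinned in {name} at {posns}")
                dirty = True
                for _try in range(50):
                    k = int(rng.integers(len(free)))
                    b = "ACGT"[int(rng.integers(4))]
                    cand = list(cod)
                    cand[free[k]] = b
                    if "".join(cand) not in STOPS:
                        write_codon(seq, posns, strand, "".join(cand))
                        break
                else:
                    raise ValueError(f"could not repair {name} codon {i}")
        if not dirty:
            return
    raise ValueError("repair did not converge")


def verify(seq: list[str]) -> None:
    assert len(seq) == L
    for name, (s, e, strand) in GENES.items():
        n = e - s + 1
        for i, posns in codon_positions(name):
            cod = read_codon(seq, posns, strand)
            if i == 0:
                assert cod == "ATG", (name, cod)
            elif n % 3 == 0 and i == n // 3 - 1:
                assert cod in STOPS, (name, cod)
            else:
                assert cod not in STOPS, (name, i, cod)
    assert seq[3106] == "N"


def main() -> None:
    pin_gene_ends()
    pin_worked_examples()
    rng = np.random.default_rng(161718)
    seq = [str(b) for b in rng.choice(list("ACGT"), size=L)]
    for p, b in PINS.items():
        seq[p - 1] = b
    repair(seq, rng)
    seq[3106] = "N"  # historical placeholder, rCRS numbering
    verify(seq)
    s = "".join(seq)
    with open(OUT, "w") as fh:
        fh.write(">chrM synthetic mitochondrial reference, rCRS coordinates "
                 "(SYNTHETIC sequence, not NC_012920.1)\n")
        for i in range(0, L, 70):
            fh.write(s[i:i + 70] + "\n")
    print(f"wrote {OUT} ({L} bp)", file=sys.stderr)


if __name__ == "__main__":
    main()
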