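"""Genetic-code model: codon sets, single-nucleotide accessibility between
amino acids, transition/transversion classes, and second-codon-position
chemistry.

The second codon position determines residue chemistry: a pyrimidine (U, C)
there confers hydrophobicity, a purine (A, G) hydrophilicity.  Every QTY-code
pair except V↔T is reachable by a single point mutation at the second
position; V↔T needs two consecutive changes in one codon, which is why no
natural V→T missense variants are expected.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product

from Bio.Data import CodonTable

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "U"}
RNA_BASES = "ACGU"

_STANDARD = CodonTable.unambiguous_rna_by_id[1]

#: codon → amino acid (one letter), 61 sense codons
GENETIC_CODE: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS: tuple[str, ...] = tuple(_STANDARD.stop_codons)

#: second-position chemistry classes (groups i–iv)
SECOND_POSITION_CLASS = {
    "U": "i_hydrophobic",
    "C": "ii_less_hydrophobic_or_hydroxyl",
    "A": "iii_hydrophilic",
    "G": "iv_water_soluble_special",
}

QTY_PAIR_SET = (("L", "Q"), ("I", "T"), ("V", "T"), ("F", "Y"))


def transcribe(codon: str) -> str:
    """Accept DNA or RNA spelling; return RNA (T→U), uppercased."""
    return codon.upper().replace("T", "U")


@lru_cache(maxsize=None)
def codons_of(aa: str) -> frozenset[str]:
    """All standard-code codons of a canonical amino acid."""
    aa = aa.upper()
    if aa in ("*", "STOP"):
        raise ValueError("stop codons have a separate accessor (STOP_CODONS)")
    codons = frozenset(c for c, a in GENETIC_CODE.items() if a == aa)
    if not codons:
        raise ValueError(f"unknown amino acid {aa!r}")
    return codons


def mutation_class(from_base: str, to_base: str) -> str:
    """'transition' (purine↔purine or pyrimidine↔pyrimidine) or 'transversion'."""
    pair = {from_base, to_base}
    if len(pair) != 2:
        raise ValueError("bases must differ")
    if pair <= PURINES or pair <= PYRIMIDINES:
        return "transition"
    return "transversion"


@dataclass(frozen=True)
class MutationPath:
    """One single-nucleotide path between codons of two amino acids."""

    from_codon: str
    to_codon: str
    position: int  # 1..3
    from_base: str
    to_base: str
    mut_class: str


def min_nt_changes(aa1: str, aa2: str) -> int:
    """Minimum Hamming distance over all codon pairs of two amino acids."""
    if aa1.upper() == aa2.upper():
        return 0
    return min(
        sum(a != b for a, b in zip(c1, c2))
        for c1, c2 in product(codons_of(aa1), codons_of(aa2))
    )


def single_step_paths(aa1: str, aa2: str) -> list[MutationPath]:
    """All codon pairs of aa1→aa2 at Hamming distance exactly 1.

    Empty when the amino acids are not single-SNV accessible.
    """
    paths = []
    for c1, c2 in product(sorted(codons_of(aa1)), sorted(codons_of(aa2))):
        diff = [i for i in range(3) if c1[i] != c2[i]]
        if len(diff) == 1:
            i = diff[0]
            paths.append(
                MutationPath(
                    from_codon=c1,
                    to_codon=c2,
                    position=i + 1,
                    from_base=c1[i],
                    to_base=c2[i],
                    mut_class=mutation_class(c1[i], c2[i]),
                )
            )
    return paths


def second_position_profile(aa: str) -> dict[str, str]:
    """Bases occurring at codon position 2 for ``aa``, with chemistry class.

    Serine's split codon family (UCx and AGU/AGC) yields both C and G and is
    therefore listed in two classes.
    """
    return {c[1]: SECOND_POSITION_CLASS[c[1]] for c in sorted(codons_of(aa))}


def qty_accessibility_report(include_reverse: bool = True) -> list[dict]:
    """Single-SNV accessibility of each QTY pair (and its reverse).

    Per pair: minimum nucleotide changes, and for accessible pairs the codon
    position(s), base change(s) and transition/transversion class.
    """
    pairs = list(QTY_PAIR_SET)
    if include_reverse:
        pairs += [(b, a) for a, b in QTY_PAIR_SET]
    rows = []
    for ref, alt in pairs:
        paths = single_step_paths(ref, alt)
        row = {
            "ref": ref,
            "alt": alt,
            "min_nt_changes": min_nt_changes(ref, alt),
            "single_snv_accessible": bool(paths),
            "positions": sorted({p.position for p in paths}),
            "base_changes": sorted({f"{p.from_base}->{p.to_base}" for p in paths}),
            "mut_classes": sorted({p.mut_class for p in paths}),
        }
        rows.append(row)
    return rows
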