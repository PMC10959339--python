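"""Exhaustive 19-substitution mutation libraries and their comparator groups.

For each chosen residue the library holds all 19 substitutions (every amino
acid except the wild type). Effect scores in [0, 1] (pph2_prob semantics:
higher = more damaging) are consumed from a score table; distributions are
summarized nonparametrically (median and interquartile range) because the
score distributions are strongly bimodal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .topology import CANONICAL_AA, ProteinRecord, Topology

AA20 = sorted(CANONICAL_AA)

#: comparator sets, exactly as defined for the forward direction
FORWARD_QTY_TARGET = {"L": "Q", "I": "T", "V": "T", "F": "Y"}
FORWARD_OTHER_POLAR = {
    "L": set("DERKHNSTY"),
    "I": set("DERKHNSQY"),
    "F": set("DERKHNSTQ"),
    # V follows the I pattern (target T); not observed in nature (needs 2 SNVs)
    "V": set("DERKHNSQY"),
}
REVERSE_QTY_TARGET = {"Q": "L", "T": "I", "Y": "F"}
NONPOLAR_SET = set("ACGILMFPWV")

ResidueKey = tuple[str, int, str]  # (protein accession, pos, ref_aa)
EntryKey = tuple[str, int, str, str]  # + alt_aa


@dataclass(frozen=True)
class SubstitutionLibrary:
    entries: tuple[EntryKey, ...]

    @property
    def residue_set_size(self) -> int:
        return len({e[:3] for e in self.entries})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["protein", "pos", "ref", "alt"])


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    median: float
    q1: float
    q3: float


def build_library(residues: list[ResidueKey]) -> SubstitutionLibrary:
    """All-19-substitutions library over the given residues.

    |entries| = 19 × |residues|; a duplicated residue is an error.
    """
    if len(set(residues)) != len(residues):
        raise ValueError("duplicate residues in library request")
    entries: list[EntryKey] = []
    for prot, pos, ref in residues:
        if ref not in CANONICAL_AA:
            raise ValueError(f"non-canonical residue {ref!r}")
        for alt in AA20:
            if alt != ref:
                entries.append((prot, pos, ref, alt))
    return SubstitutionLibrary(entries=tuple(entries))


def select_tm_hydrophobics(
    proteins: list[ProteinRecord],
    topologies: dict[str, Topology],
    alphabet: str = "LIVF",
) -> list[ResidueKey]:
    """All TM-helix positions whose residue is in ``alphabet`` (default the
    four QTY-code targets L, I, V, F)."""
    out: list[ResidueKey] = []
    for prot in proteins:
        topo = topologies[prot.accession]
        for pos in topo.tm_positions():
            aa = prot.residue(pos)
            if aa in alphabet:
                out.append((prot.accession, pos, aa))
    return out


def comparator_groups(ref_aa: str, direction: str = "forward") -> dict[str, set[str]]:
    """Named alternate-residue groups for one wild-type residue.

    Forward (L/I/V/F): the QTY target plus the fixed other-polar comparator
    set; reverse (Q/T/Y): the rQTY target plus the other nonpolar residues.
    ``all19`` is every alternate.
    """
    ref_aa = ref_aa.upper()
    all19 = set(AA20) - {ref_aa}
    if direction == "forward":
        if ref_aa not in FORWARD_QTY_TARGET:
            raise ValueError(f"{ref_aa} is not a forward QTY-code residue")
        return {
            "qty_target": {FORWARD_QTY_TARGET[ref_aa]},
            "other_polar": set(FORWARD_OTHER_POLAR[ref_aa]),
            "all19": all19,
        }
    if direction == "reverse":
        if ref_aa not in REVERSE_QTY_TARGET:
            raise ValueError(f"{ref_aa} is not a reverse QTY-code residue")
        target = REVERSE_QTY_TARGET[ref_aa]
        return {
            "qty_target": {target},
            "other_nonpolar": (NONPOLAR_SET - {target}) - {ref_aa},
            "all19": all19,
        }
    raise ValueError("direction must be 'forward' or 'reverse'")


class ScoreTable(dict):
    """Mapping (protein, pos, ref, alt) → effect score in [0, 1]."""

    def __setitem__(self, key: EntryKey, value: float) -> None:
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"score {value} outside [0,1] for {key}")
        super().__setitem__(key, value)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ScoreTable":
        table = cls()
        for _, r in df.iterrows():
            table[(str(r["protein"]), int(r["pos"]), str(r["ref"]), str(r["alt"]))] = float(
                r["score"]
            )
        return table


def _summary(name: str, values: np.ndarray) -> GroupSummary:
    # quartiles by linear interpolation between order statistics ("type 7")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    return GroupSummary(group=name, n=len(values), median=float(med), q1=float(q1), q3=float(q3))


def summarize_groups(
    library: SubstitutionLibrary,
    scores: ScoreTable,
    direction: str = "forward",
) -> list[GroupSummary]:
    """Median/IQR of effect scores per comparator group, pooled over the
    library's residues."""
    missing = [e for e in library.entries if e not in scores]
    if missing:
        raise ValueError(f"{len(missing)} unscored entries, first: {missing[:3]}")
    grouped: dict[str, list[float]] = {}
    for entry in library.entries:
        _, _, ref, alt = entry
        groups = comparator_groups(ref, direction)
        for name, members in groups.items():
            if alt in members:
                grouped.setdefault(name, []).append(scores[entry])
    return [_summary(name, np.asarray(vals)) for name, vals in sorted(grouped.items())]
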