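"""Protein sequences, membrane topology, and residue-to-region resolution.

A membrane transporter is represented as a :class:`ProteinRecord` (1-based
residue numbering over the 20 canonical amino acids) plus a :class:`Topology`:
a set of non-overlapping segments of kind TM_HELIX, EXTRACELLULAR or
CYTOPLASMIC, UniProt-style with 1-based inclusive coordinates.

Region resolution follows the molecular-architecture naming used for
monoamine transporters: TM helices are numbered TM1..TMn in sequence order,
loops between consecutive helices alternate sides and are numbered ECL1,
ICL1, ... per side, residues before the first helix on the cytoplasmic side
are N_TERM and after the last are C_TERM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")

TM_HELIX = "TM_HELIX"
EXTRACELLULAR = "EXTRACELLULAR"
CYTOPLASMIC = "CYTOPLASMIC"
SEGMENT_KINDS = (TM_HELIX, EXTRACELLULAR, CYTOPLASMIC)


class TopologyError(ValueError):
    """Invalid topology annotation (overlap, range, unknown kind)."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with 1-based residue numbering."""

    accession: str
    name: str
    sequence: str

    def __post_init__(self) -> None:
        for i, aa in enumerate(self.sequence, start=1):
            if aa not in CANONICAL_AA:
                raise ValueError(f"invalid residue {aa} at {i}")
        if not self.sequence:
            raise ValueError("empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def residue(self, pos: int) -> str:
        """One-letter residue at 1-based position ``pos``."""
        if not 1 <= pos <= self.length:
            raise IndexError(f"position {pos} outside 1..{self.length}")
        return self.sequence[pos - 1]


@dataclass(frozen=True)
class TopologySegment:
    kind: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise TopologyError(f"unknown segment kind {self.kind!r}")
        if self.start < 1 or self.start > self.end:
            raise TopologyError(
                f"bad segment range {self.start}-{self.end} (1-based inclusive)"
            )

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class RegionLabel:
    """Architectural region of one residue, e.g. TM8 or ECL3."""

    category: str  # TM | ECL | ICL | N_TERM | C_TERM | UNANNOTATED
    ordinal: int | None = None

    def __post_init__(self) -> None:
        if self.category in ("TM", "ECL", "ICL"):
            if self.ordinal is None or self.ordinal < 1:
                raise ValueError(f"{self.category} label requires a positive ordinal")
        elif self.ordinal is not None:
            raise ValueError(f"{self.category} label must not carry an ordinal")

    def __str__(self) -> str:
        if self.ordinal is not None:
            return f"{self.category}{self.ordinal}"
        return self.category

    @property
    def is_tm(self) -> bool:
        return self.category == "TM"


@dataclass
class Topology:
    """Validated, sorted set of topology segments for one protein."""

    protein_length: int
    segments: tuple[TopologySegment, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        segs = tuple(sorted(self.segments, key=lambda s: s.start))
        for s in segs:
            if s.end > self.protein_length:
                raise TopologyError(
                    f"segment {s.kind} {s.start}-{s.end} exceeds protein "
                    f"length {self.protein_length}"
                )
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise TopologyError(
                    f"overlapping segments {a.kind} {a.start}-{a.end} and "
                    f"{b.kind} {b.start}-{b.end}"
                )
        self.segments = segs
        self._labels = _resolve_labels(self)

    @property
    def tm_segments(self) -> tuple[TopologySegment, ...]:
        return tuple(s for s in self.segments if s.kind == TM_HELIX)

    def tm_positions(self) -> list[int]:
        """All 1-based positions inside TM helices, ascending."""
        out: list[int] = []
        for s in self.tm_segments:
            out.extend(range(s.start, s.end + 1))
        return out

    def locate(self, pos: int) -> RegionLabel:
        if not 1 <= pos <= self.protein_length:
            raise IndexError(f"position {pos} outside 1..{self.protein_length}")
        return self._labels[pos - 1]


def _resolve_labels(topo: Topology) -> list[RegionLabel]:
    """Assign one RegionLabel per residue (total function, no gaps)."""
    n = topo.protein_length
    tms = topo.tm_segments
    labels: list[RegionLabel | None] = [None] * n

    # explicit annotation lookup for inferring sides
    def annotated_kind(pos: int) -> str | None:
        for s in topo.segments:
            if pos in s:
                return s.kind
        return None

    for ordinal, s in enumerate(tms, start=1):
        for p in range(s.start, s.end + 1):
            labels[p - 1] = RegionLabel("TM", ordinal)

    if not tms:
        for i in range(n):
            if labels[i] is None:
                kind = annotated_kind(i + 1)
                labels[i] = RegionLabel("UNANNOTATED")
        return [lab for lab in labels if lab is not None]

    # termini
    first, last = tms[0], tms[-1]
    for p in range(1, first.start):
        kind = annotated_kind(p)
        if kind == CYTOPLASMIC:
            labels[p - 1] = RegionLabel("N_TERM")
        else:
            labels[p - 1] = RegionLabel("UNANNOTATED")
    for p in range(last.end + 1, n + 1):
        kind = annotated_kind(p)
        labels[p - 1] = RegionLabel("C_TERM") if kind == CYTOPLASMIC else RegionLabel(
            "UNANNOTATED"
        )

    # loops between consecutive TM helices: side from annotation when present,
    # otherwise alternating from the previous loop's side
    prev_side: str | None = None
    if first.start > 1:
        nk = annotated_kind(first.start - 1)
        if nk == CYTOPLASMIC:
            prev_side = "IC"
        elif nk == EXTRACELLULAR:
            prev_side = "EC"
    ecl = icl = 0
    for a, b in zip(tms, tms[1:]):
        lo, hi = a.end + 1, b.start - 1
        if lo > hi:
            # adjacent helices: still flips side
            prev_side = _flip(prev_side)
            continue
        kinds = {annotated_kind(p) for p in range(lo, hi + 1)} - {None}
        if EXTRACELLULAR in kinds:
            side = "EC"
        elif CYTOPLASMIC in kinds:
            side = "IC"
        else:
            side = _flip(prev_side)
        if side == "EC":
            ecl += 1
            lab = RegionLabel("ECL", ecl)
        elif side == "IC":
            icl += 1
            lab = RegionLabel("ICL", icl)
        else:
            lab = RegionLabel("UNANNOTATED")
        for p in range(lo, hi + 1):
            labels[p - 1] = lab
        prev_side = side
    return [lab if lab is not None else RegionLabel("UNANNOTATED") for lab in labels]


def _flip(side: str | None) -> str | None:
    if side == "EC":
        return "IC"
    if side == "IC":
        return "EC"
    return None


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (multi-)FASTA file into validated protein records.

    Sequences are uppercased; any gap or ambiguity character raises with the
    offending character and its 1-based position.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA entries in {path}")
    out = []
    for rec in records:
        seq = str(rec.seq).upper()
        name = rec.description.split(maxsplit=1)[1] if " " in rec.description else rec.id
        out.append(ProteinRecord(accession=rec.id, name=name, sequence=seq))
    return out


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession} {rec.name}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_topology(path: str | Path, protein: ProteinRecord) -> Topology:
    """Read a topology annotation (TSV with kind/start/end columns, or a JSON
    list of objects with the same keys) and validate it against ``protein``.

    Coordinates are 1-based inclusive (UniProt convention).
    """
    path = Path(path)
    text = path.read_text()
    rows: list[dict]
    if text.lstrip().startswith("["):
        rows = json.loads(text)
    else:
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines:
            raise TopologyError(f"empty topology file {path}")
        header = lines[0].split("\t")
        required = {"kind", "start", "end"}
        if not required <= set(header):
            raise TopologyError(f"topology TSV must have columns {sorted(required)}")
        rows = [dict(zip(header, ln.split("\t"))) for ln in lines[1:]]
    segs = [
        TopologySegment(kind=str(r["kind"]), start=int(r["start"]), end=int(r["end"]))
        for r in rows
    ]
    return Topology(protein_length=protein.length, segments=tuple(segs))


def topology_from_rows(rows: Sequence[tuple[str, int, int]], length: int) -> Topology:
    """Build a topology directly from (kind, start, end) tuples."""
    return Topology(
        protein_length=length,
        segments=tuple(TopologySegment(k, s, e) for k, s, e in rows),
    )


def locate_residue(topology: Topology, pos: int) -> RegionLabel:
    """Region label of the residue at 1-based ``pos``."""
    return topology.locate(pos)
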