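"""The QTY and reverse-QTY substitution codes.

The QTY code renders a membrane protein water-soluble by replacing the
hydrophobic residues of its transmembrane helices with hydrophilic ones of
near-identical shape: L→Q, V→T, I→T, F→Y.  The reverse code maps back
Q→L, T→I, Y→F (threonine always reverts to isoleucine, never valine, since
only T↔I is reachable by a single nucleotide change).  Both maps stay inside
the uncharged alphabet {Q,T,Y,L,I,F}, so the design never introduces charge.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .topology import ProteinRecord, RegionLabel, Topology

QTY_FORWARD = {"L": "Q", "V": "T", "I": "T", "F": "Y"}
QTY_REVERSE = {"Q": "L", "T": "I", "Y": "F"}

#: Ordered-pair view used for variant direction classification.
QTY_PAIRS = tuple(QTY_FORWARD.items())  # (L,Q) (V,T) (I,T) (F,Y)
RQTY_PAIRS = (("Q", "L"), ("T", "I"), ("T", "V"), ("Y", "F"))


@dataclass(frozen=True)
class SubstitutionEvent:
    pos: int  # 1-based
    ref_aa: str
    alt_aa: str
    region: RegionLabel

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValueError("substitution must change the residue")


@dataclass(frozen=True)
class VariationStats:
    n_substitutions: int
    tm_variation_pct: float
    overall_variation_pct: float


def _apply_map(
    protein: ProteinRecord,
    topology: Topology,
    mapping: dict[str, str],
    suffix: str,
    tm_only: bool = True,
) -> tuple[ProteinRecord, list[SubstitutionEvent]]:
    seq = list(protein.sequence)
    events: list[SubstitutionEvent] = []
    if tm_only:
        positions = topology.tm_positions()
    else:
        positions = range(1, protein.length + 1)
    for pos in positions:
        ref = seq[pos - 1]
        alt = mapping.get(ref)
        if alt is not None:
            seq[pos - 1] = alt
            events.append(
                SubstitutionEvent(pos=pos, ref_aa=ref, alt_aa=alt, region=topology.locate(pos))
            )
    variant = replace(
        protein, accession=protein.accession + suffix, sequence="".join(seq)
    )
    return variant, events


def apply_qty(
    protein: ProteinRecord, topology: Topology, tm_only: bool = True
) -> tuple[ProteinRecord, list[SubstitutionEvent]]:
    """Apply L→Q, V→T, I→T, F→Y inside TM helices.

    ``tm_only=False`` applies the map over the whole sequence; this is
    non-canonical and meant for experimentation only.
    """
    return _apply_map(protein, topology, QTY_FORWARD, "_QTY", tm_only)


def apply_rqty(
    protein: ProteinRecord, topology: Topology, tm_only: bool = True
) -> tuple[ProteinRecord, list[SubstitutionEvent]]:
    """Apply the reverse code Q→L, T→I, Y→F inside TM helices."""
    return _apply_map(protein, topology, QTY_REVERSE, "_rQTY", tm_only)


def _round_half_up(x: float, ndigits: int) -> float:
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def variation_stats(
    events: list[SubstitutionEvent], protein: ProteinRecord, topology: Topology
) -> VariationStats:
    """TM and overall variation percentages for a set of substitutions.

    TM variation = events inside TM helices / total TM residues; overall
    variation = events / protein length. Both in percent, two decimals,
    half-up rounding.
    """
    n_tm_res = len(topology.tm_positions())
    n_tm_events = sum(1 for e in events if e.region.is_tm)
    if n_tm_events and not n_tm_res:
        raise ValueError("TM-located events but topology has zero TM residues")
    tm_pct = _round_half_up(100.0 * n_tm_events / n_tm_res, 2) if n_tm_res else 0.0
    overall_pct = _round_half_up(100.0 * len(events) / protein.length, 2)
    return VariationStats(
        n_substitutions=len(events),
        tm_variation_pct=tm_pct,
        overall_variation_pct=overall_pct,
    )
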