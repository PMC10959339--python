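"""Alignment-column statistics for QTY-code residue pairs.

For a pair such as (L, Q) each retained alignment column contributes one
observation: the frequencies of the two residues among that column's non-gap
characters.  Monotone association between the two frequency vectors is
measured by Spearman's ρ, and by the partial Spearman ρ holding a per-column
conservation score (ConSurf grades or an internal entropy-based fallback)
fixed, with a seeded percentile bootstrap over columns for the CI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from . import stats
from .topology import CANONICAL_AA

GAP_CHARS = set("-.")


@dataclass(frozen=True)
class Alignment:
    rows: tuple[str, ...]
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)


@dataclass(frozen=True)
class ConservationVector:
    scores: tuple[float, ...]
    scale: str  # CONSURF_GRADE_1_9 | INTERNAL_ENTROPY

    def __post_init__(self) -> None:
        if self.scale == "CONSURF_GRADE_1_9":
            for s in self.scores:
                if not (np.isnan(s) or (1 <= s <= 9 and float(s).is_integer())):
                    raise ValueError("ConSurf grades must be integers in 1..9")
        elif self.scale == "INTERNAL_ENTROPY":
            for s in self.scores:
                if not (np.isnan(s) or 0.0 <= s <= 1.0):
                    raise ValueError("entropy conservation must lie in [0,1]")
        else:
            raise ValueError(f"unknown conservation scale {self.scale!r}")


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA; rows uppercased, equal lengths enforced."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no alignment rows in {path}")
    return Alignment(
        rows=tuple(str(r.seq).upper() for r in records),
        ids=tuple(r.id for r in records),
    )


def pair_vectors(
    aln: Alignment, pair: tuple[str, str], min_occupancy: float = 0.5
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Per-column frequencies of the two pair members among non-gap residues.

    Columns whose non-gap occupancy is below ``min_occupancy`` are dropped.
    Returns (x, y, kept_column_indices); x + y <= 1 per column.
    """
    aa1, aa2 = (a.upper() for a in pair)
    if aa1 == aa2:
        raise ValueError("pair members must be distinct")
    x, y, kept = [], [], []
    for j in range(aln.n_cols):
        col = aln.column(j)
        residues = [c for c in col if c not in GAP_CHARS]
        occ = len(residues) / aln.n_rows
        if occ < min_occupancy or not residues:
            continue
        n = len(residues)
        x.append(sum(c == aa1 for c in residues) / n)
        y.append(sum(c == aa2 for c in residues) / n)
        kept.append(j)
    if not kept:
        raise ValueError("no columns retained at this occupancy threshold")
    return np.asarray(x), np.asarray(y), kept


def internal_conservation(aln: Alignment) -> ConservationVector:
    """1 − normalized Shannon entropy of each column's non-gap composition.

    1.0 for an invariant column, 0.0 for a uniform 20-residue column; NaN for
    an all-gap column.  This is an alignment-internal score, not a
    phylogeny-aware conservation estimate.
    """
    max_h = np.log(20.0)
    scores = []
    for j in range(aln.n_cols):
        residues = [c for c in aln.column(j) if c not in GAP_CHARS]
        if not residues:
            scores.append(float("nan"))
            continue
        counts = np.array(
            [residues.count(a) for a in sorted(set(residues))], dtype=float
        )
        p = counts / counts.sum()
        h = -np.sum(p * np.log(p))
        scores.append(float(1.0 - h / max_h))
    return ConservationVector(scores=tuple(scores), scale="INTERNAL_ENTROPY")


def pair_correlation(
    aln: Alignment,
    pair: tuple[str, str],
    conservation: ConservationVector | None = None,
    min_occupancy: float = 0.5,
    n_boot: int = 1000,
    seed: int = 0,
) -> stats.CorrelationResult:
    """Spearman ρ of the pair-member frequency vectors, the partial ρ given
    per-column conservation, and a bootstrap CI on ρ over columns.

    ``conservation`` must cover all pre-filter columns; the same column
    filter is applied to it.  With no conservation given, the internal
    entropy score is used.
    """
    x, y, kept = pair_vectors(aln, pair, min_occupancy)
    if conservation is None:
        conservation = internal_conservation(aln)
    if len(conservation.scores) != aln.n_cols:
        raise ValueError("conservation length must equal the alignment width")
    z = np.asarray([conservation.scores[j] for j in kept])
    if np.any(np.isnan(z)):
        raise ValueError("conservation undefined on a retained column")
    base = stats.spearman(x, y)
    partial = stats.partial_spearman(x, y, z)
    data = np.column_stack([x, y])
    lo, hi = stats.bootstrap_ci(
        lambda d: float(np.clip(_safe_spearman(d), -1, 1)),
        data,
        n_boot=n_boot,
        seed=seed,
    )
    return stats.CorrelationResult(
        rho=base.rho,
        n=base.n,
        p_value=base.p_value,
        partial_rho=partial.partial_rho,
        ci_low=min(lo, base.rho),
        ci_high=max(hi, base.rho),
        n_bootstrap=n_boot,
    )


def _safe_spearman(d: np.ndarray) -> float:
    from scipy.stats import spearmanr

    rho = spearmanr(d[:, 0], d[:, 1]).statistic
    return 0.0 if np.isnan(rho) else float(rho)
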