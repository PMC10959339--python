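"""CA-based rigid superposition (Kabsch) and RMSD between structure pairs.

A single all-pairs least-squares fit over matched CA atoms: center both
point sets, take the SVD of the covariance, and correct the sign of the
smallest singular vector so the rotation is proper (determinant +1, no
reflection).  No outlier-rejection cycles — the fit is deterministic and
directly checkable against independent optimizers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class CoordinateSet:
    """Ordered residue-number → CA coordinate mapping for one chain."""

    residues: tuple[int, ...]
    coords: np.ndarray  # (n, 3) Å
    chain: str = "A"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.residues), 3):
            raise ValueError("coords must be (n_residues, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if any(b <= a for a, b in zip(self.residues, self.residues[1:])):
            raise ValueError("residue numbers must be strictly increasing")


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # (3,3), proper
    translation: np.ndarray  # (3,)
    rmsd: float  # Å
    n_pairs: int


def read_ca(path: str | Path, chain: str | None = None) -> CoordinateSet:
    """CA coordinates from PDB ATOM records, one per residue.

    Alternate locations are resolved to the highest-occupancy conformer
    (first seen wins ties).  HETATM records are ignored.
    """
    best: dict[int, tuple[float, np.ndarray]] = {}
    chain_seen = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("ATOM"):
                continue
            atom_name = line[12:16].strip()
            if atom_name != "CA":
                continue
            ch = line[21].strip() or "A"
            if chain is not None and ch != chain:
                continue
            if chain is None:
                if chain_seen is None:
                    chain_seen = ch
                elif ch != chain_seen:
                    continue
            resseq = int(line[22:26])
            try:
                occ = float(line[54:60])
            except ValueError:
                occ = 1.0
            xyz = np.array(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            )
            if resseq not in best or occ > best[resseq][0]:
                best[resseq] = (occ, xyz)
    if not best:
        raise ValueError(f"no CA ATOM records in {path}")
    residues = tuple(sorted(best))
    coords = np.array([best[r][1] for r in residues])
    return CoordinateSet(residues=residues, coords=coords, chain=chain or chain_seen or "A")


def pair_common(
    a: CoordinateSet,
    b: CoordinateSet,
    trim: list[tuple[int, int]] | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[int, ...]]:
    """Coordinate arrays over residues present in both sets, minus trimmed
    1-based-inclusive ranges, ordered by residue number."""
    trimmed = set()
    for lo, hi in trim or []:
        trimmed.update(range(lo, hi + 1))
    common = [r for r in a.residues if r in set(b.residues) and r not in trimmed]
    if len(common) < 3:
        raise ValueError(f"only {len(common)} common residues; need at least 3")
    ia = {r: i for i, r in enumerate(a.residues)}
    ib = {r: i for i, r in enumerate(b.residues)}
    pa = a.coords[[ia[r] for r in common]]
    pb = b.coords[[ib[r] for r in common]]
    return pa, pb, tuple(common)


def kabsch_superpose(moving: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal proper rotation R and translation t minimizing
    ||R·moving + t − target||; returns the post-fit RMSD.

    Degenerate (collinear) point sets are rejected: the optimal rotation is
    then not unique.
    """
    p = np.asarray(moving, dtype=float)
    q = np.asarray(target, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("need matched (n, 3) arrays")
    n = p.shape[0]
    if n < 3:
        raise ValueError("need at least 3 pairs")
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    # collinearity check on either set
    for arr, name in ((p0, "moving"), (q0, "target")):
        s = np.linalg.svd(arr, compute_uv=False)
        if s[1] <= 1e-8 * max(s[0], 1.0):
            raise ValueError(f"{name} points are (near-)collinear; rotation not unique")
    h = p0.T @ q0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    t = qc - rot @ pc
    moved = (rot @ p.T).T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=t, rmsd=rmsd, n_pairs=n)


def superpose_sets(
    a: CoordinateSet,
    b: CoordinateSet,
    trim: list[tuple[int, int]] | None = None,
) -> SuperpositionResult:
    """Pair common residues of two coordinate sets and superpose a onto b."""
    pa, pb, _ = pair_common(a, b, trim)
    return kabsch_superpose(pa, pb)
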