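"""Seeded synthetic-data generators.

Each generator emulates the statistical structure one pipeline stage
assumes — toy transporters with planted TM hydrophobic content, variant
tables with known QTY/rQTY composition, Beta-distributed effect-score tables
with planted group medians, alignments with planted pair coupling and a
conservation confounder, and rigid-transform-related CA point clouds.  Every
generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.transform import Rotation

from .mutlib import AA20, ScoreTable, SubstitutionLibrary
from .qty import QTY_FORWARD, QTY_REVERSE
from .topology import (
    CYTOPLASMIC,
    EXTRACELLULAR,
    TM_HELIX,
    ProteinRecord,
    Topology,
    TopologySegment,
)

HYDROPHOBIC_QTY = "LIVF"
#: residues used for unplanted TM positions: neither forward nor reverse
#: QTY-code members, so substitution counts stay exactly the planted ones
NEUTRAL_TM = sorted(set(AA20) - set("LIVFQTY"))


def make_toy_transporter(
    seed: int,
    n_tm: int = 12,
    tm_len: int = 21,
    loop_len: int = 10,
    hydrophobic_frac: float = 0.5,
    first_side: str = "IC",
) -> tuple[ProteinRecord, Topology]:
    """Toy membrane protein with ``n_tm`` planted TM helices.

    Layout: loop, (TM, loop) × n_tm, with loop sides alternating from
    ``first_side`` ("IC" = cytoplasmic N-terminus, the transporter
    architecture).  TM residues are L/I/V/F with probability
    ``hydrophobic_frac`` (uniform over the four) and otherwise drawn from
    residues outside both QTY maps; loops are uniform over all 20.
    """
    if n_tm < 1:
        raise ValueError("n_tm must be >= 1")
    if not 0.0 <= hydrophobic_frac <= 1.0:
        raise ValueError("hydrophobic_frac must lie in [0,1]")
    if first_side not in ("IC", "EC"):
        raise ValueError("first_side must be 'IC' or 'EC'")
    rng = np.random.default_rng(seed)
    seq: list[str] = []
    segments: list[TopologySegment] = []
    side = first_side
    pos = 1

    def add_loop() -> None:
        nonlocal pos, side
        kind = CYTOPLASMIC if side == "IC" else EXTRACELLULAR
        segments.append(TopologySegment(kind, pos, pos + loop_len - 1))
        seq.extend(rng.choice(AA20, size=loop_len))
        pos += loop_len
        side = "EC" if side == "IC" else "IC"

    add_loop()
    for _ in range(n_tm):
        segments.append(TopologySegment(TM_HELIX, pos, pos + tm_len - 1))
        for _ in range(tm_len):
            if rng.random() < hydrophobic_frac:
                seq.append(rng.choice(list(HYDROPHOBIC_QTY)))
            else:
                seq.append(rng.choice(NEUTRAL_TM))
        pos += tm_len
        add_loop()

    protein = ProteinRecord(
        accession=f"TOY{seed}", name="synthetic toy transporter", sequence="".join(seq)
    )
    topo = Topology(protein_length=protein.length, segments=tuple(segments))
    return protein, topo


def make_variant_table(
    seed: int,
    n_qty: int,
    n_rqty: int,
    n_other: int,
    protein: ProteinRecord,
    topology: Topology,
) -> pd.DataFrame:
    """Variant table with a planted QTY/rQTY/other composition.

    Positions are sampled without replacement from residues eligible for
    each direction; location comes from the topology, structure is α-helix
    inside TM and loop outside, effects are drawn from a fixed categorical
    distribution (benign .45, possibly damaging .25, probably damaging .30).
    """
    rng = np.random.default_rng(seed)
    fwd_pos = [p for p in range(1, protein.length + 1) if protein.residue(p) in QTY_FORWARD]
    rev_pos = [p for p in range(1, protein.length + 1) if protein.residue(p) in QTY_REVERSE]
    other_pos = [p for p in range(1, protein.length + 1)]
    if n_qty > len(fwd_pos):
        raise ValueError(f"only {len(fwd_pos)} residues eligible for QTY variants")
    if n_rqty > len(rev_pos):
        raise ValueError(f"only {len(rev_pos)} residues eligible for rQTY variants")

    rows = []

    def emit(pos: int, alt: str) -> None:
        ref = protein.residue(pos)
        label = topology.locate(pos)
        structure = "α-helix" if label.is_tm else "loop"
        effect = rng.choice(["benign", "? damaging", "damaging"], p=[0.45, 0.25, 0.30])
        rows.append(
            {
                "protein": protein.accession,
                "mutation": f"{ref}{pos}{alt}",
                "location": str(label) if label.ordinal is not None else "Intracellular"
                if label.category in ("N_TERM", "C_TERM")
                else "-",
                "structure": structure,
                "exposure": "-",
                "conservation_grade": int(rng.integers(1, 10)),
                "effect": effect,
                "clinical": "-",
                "maf": round(float(rng.uniform(0, 0.01)), 5),
            }
        )

    for pos in rng.choice(fwd_pos, size=n_qty, replace=False):
        emit(int(pos), QTY_FORWARD[protein.residue(int(pos))])
    for pos in rng.choice(rev_pos, size=n_rqty, replace=False):
        emit(int(pos), QTY_REVERSE[protein.residue(int(pos))])
    emitted = 0
    for pos in rng.permutation(other_pos):
        if emitted >= n_other:
            break
        ref = protein.residue(int(pos))
        alts = [
            a
            for a in AA20
            if a != ref
            and QTY_FORWARD.get(ref) != a
            and QTY_REVERSE.get(ref) != a
            and a != {"T": "V"}.get(ref)  # T→V is rQTY by definition
        ]
        emit(int(pos), str(rng.choice(alts)))
        emitted += 1
    if emitted < n_other:
        raise ValueError("not enough residues for requested 'other' variants")
    return pd.DataFrame(rows)


def _beta_params_from_median(median: float, concentration: float) -> tuple[float, float]:
    """Invert Beta(a, k−a) so the distribution median equals ``median``."""
    if not 0.0 < median < 1.0:
        raise ValueError("median must lie in (0,1)")
    k = concentration
    lo, hi = 1e-6, k - 1e-6

    def med(a: float) -> float:
        return float(sps.beta.ppf(0.5, a, k - a))

    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if med(mid) < median:
            lo = mid
        else:
            hi = mid
    a = 0.5 * (lo + hi)
    return a, k - a


def make_score_table(
    seed: int,
    library: SubstitutionLibrary,
    qty_median: float = 0.3,
    other_median: float = 0.9,
    concentration: float = 2.0,
) -> ScoreTable:
    """Effect scores with planted group medians.

    QTY-target entries (alt is the wild type's QTY/rQTY partner) draw from a
    Beta with median ``qty_median``; every other entry from a Beta with
    median ``other_median``; ``concentration`` (= a + b) controls spread.
    """
    rng = np.random.default_rng(seed)
    a_q, b_q = _beta_params_from_median(qty_median, concentration)
    a_o, b_o = _beta_params_from_median(other_median, concentration)
    table = ScoreTable()
    for entry in library.entries:
        _, _, ref, alt = entry
        is_qty = QTY_FORWARD.get(ref) == alt or QTY_REVERSE.get(ref) == alt
        a, b = (a_q, b_q) if is_qty else (a_o, b_o)
        table[entry] = float(rng.beta(a, b))
    return table


def make_msa(
    seed: int,
    n_rows: int = 50,
    n_cols: int = 500,
    pair: tuple[str, str] = ("L", "Q"),
    coupling: float = 0.0,
    confounder_strength: float = 0.0,
):
    """Alignment with planted monotone coupling between the frequencies of a
    residue pair, plus a latent per-column conservation confounder.

    Per column: a conservation latent c ~ U(0,1) and a coupling latent
    t ~ U(0,1) are drawn; each pair member's frequency mixes independent
    noise, the coupling latent (t for the first member, t or 1−t per the
    coupling sign for the second) and c (weight ``confounder_strength``).
    Rows are drawn i.i.d. from the column distribution (no phylogeny).
    Returns (Alignment, ConservationVector with the true latent c).
    """
    from .msa import Alignment, ConservationVector

    if not -1.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [-1,1]")
    if not 0.0 <= confounder_strength <= 1.0:
        raise ValueError("confounder_strength must lie in [0,1]")
    rng = np.random.default_rng(seed)
    aa1, aa2 = (a.upper() for a in pair)
    others = [a for a in AA20 if a not in (aa1, aa2)]
    cols = []
    cons = []
    w = abs(coupling)
    g = confounder_strength
    for _ in range(n_cols):
        c = rng.uniform()
        t = rng.uniform()
        u1, u2 = rng.uniform(), rng.uniform()
        s1 = (1 - w) * u1 + w * t
        s2 = (1 - w) * u2 + w * (t if coupling >= 0 else 1.0 - t)
        s1 = (1 - g) * s1 + g * c
        s2 = (1 - g) * s2 + g * c
        p1, p2 = 0.45 * s1, 0.45 * s2  # keep p1 + p2 < 1
        draws = rng.uniform(size=n_rows)
        col = np.where(
            draws < p1, aa1, np.where(draws < p1 + p2, aa2, rng.choice(others, size=n_rows))
        )
        cols.append(col)
        cons.append(c)
    mat = np.array(cols).T  # rows × cols
    rows = tuple("".join(r) for r in mat)
    aln = Alignment(rows=rows, ids=tuple(f"seq{i}" for i in range(n_rows)))
    return aln, ConservationVector(scores=tuple(cons), scale="INTERNAL_ENTROPY")


def make_coordinates(
    seed: int,
    n: int = 100,
    rotation_deg: float = 30.0,
    translation: tuple[float, float, float] = (5.0, -3.0, 2.0),
    noise_sd: float = 0.0,
) -> tuple["CoordinateSet", "CoordinateSet"]:
    """Helical-arc CA point cloud and a rigid-transformed, noise-perturbed
    copy (isotropic Gaussian, per-coordinate σ = ``noise_sd`` Å)."""
    from .superpose import CoordinateSet

    if n < 3:
        raise ValueError("need at least 3 points")
    rng = np.random.default_rng(seed)
    i = np.arange(n)
    # idealized alpha-helix: 2.3 Å radius, 1.5 Å rise, 100° per residue,
    # bent into a gentle arc so the cloud is never collinear
    theta = np.deg2rad(100.0 * i)
    pts = np.column_stack(
        [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i + 0.01 * i**1.5]
    )
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    rot = Rotation.from_rotvec(np.deg2rad(rotation_deg) * axis).as_matrix()
    moved = (rot @ pts.T).T + np.asarray(translation)
    if noise_sd > 0:
        moved = moved + rng.normal(scale=noise_sd, size=moved.shape)
    residues = tuple(range(1, n + 1))
    return (
        CoordinateSet(residues=residues, coords=pts),
        CoordinateSet(residues=residues, coords=moved),
    )
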