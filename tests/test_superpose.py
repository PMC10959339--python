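import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from qtykit import synth
from qtykit.superpose import (
    CoordinateSet,
    kabsch_superpose,
    pair_common,
    read_ca,
    superpose_sets,
)


def _pdb_line(serial, resseq, x, y, z, altloc=" ", occ=1.0, name="CA"):
    return (
        f"ATOM  {serial:>5} {name:^4}{altloc}ALA A{resseq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f} 20.00           C\n"
    )


def test_read_ca_minimal(tmp_path):
    p = tmp_path / "m.pdb"
    p.write_text(
        _pdb_line(1, 1, 0, 0, 0)
        + _pdb_line(2, 2, 1, 0, 0)
        + _pdb_line(3, 2, 9, 9, 9, name="CB")  # non-CA ignored
        + _pdb_line(4, 3, 2, 1, 0)
    )
    cs = read_ca(p)
    assert cs.residues == (1, 2, 3)
    assert cs.coords.shape == (3, 3)


def test_read_ca_altloc_highest_occupancy(tmp_path):
    p = tmp_path / "alt.pdb"
    p.write_text(
        _pdb_line(1, 1, 0, 0, 0, altloc="A", occ=0.6)
        + _pdb_line(2, 1, 5, 5, 5, altloc="B", occ=0.4)
        + _pdb_line(3, 2, 1, 0, 0)
        + _pdb_line(4, 3, 2, 2, 0)
    )
    cs = read_ca(p)
    assert tuple(cs.coords[0]) == (0.0, 0.0, 0.0)


def test_read_ca_hetatm_only_errors(tmp_path):
    p = tmp_path / "het.pdb"
    p.write_text("HETATM    1  CA  CA  A 101      0.000   0.000   0.000  1.00 20.00\n")
    with pytest.raises(ValueError, match="no CA"):
        read_ca(p)


def test_pair_common_and_trim():
    a = CoordinateSet(residues=(1, 2, 3, 4, 5), coords=np.random.default_rng(0).normal(size=(5, 3)))
    b = CoordinateSet(residues=(2, 3, 4, 5, 6), coords=np.random.default_rng(1).normal(size=(5, 3)))
    pa, pb, common = pair_common(a, b)
    assert common == (2, 3, 4, 5)
    pa2, pb2, common2 = pair_common(a, b, trim=[(2, 2)])
    assert common2 == (3, 4, 5)
    disjoint = CoordinateSet(residues=(10, 11, 12), coords=np.eye(3))
    with pytest.raises(ValueError, match="common"):
        pair_common(a, disjoint)


def test_kabsch_identical_sets_zero_rmsd():
    pts, _ = synth.make_coordinates(0, n=30)
    res = kabsch_superpose(pts.coords, pts.coords)
    assert res.rmsd < 1e-9
    assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)


def test_kabsch_recovers_rigid_motion():
    a, b = synth.make_coordinates(1, n=50, rotation_deg=37.0, noise_sd=0.0)
    res = superpose_sets(a, b)
    assert res.rmsd < 1e-6
    assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)


def test_rmsd_symmetric_and_rotation_invariant():
    a, b = synth.make_coordinates(2, n=80, noise_sd=0.3)
    fwd = kabsch_superpose(a.coords, b.coords).rmsd
    bwd = kabsch_superpose(b.coords, a.coords).rmsd
    assert fwd == pytest.approx(bwd, abs=1e-9)
    rot = Rotation.from_euler("xyz", [10, 40, 70], degrees=True).as_matrix()
    pre_rotated = (rot @ a.coords.T).T
    assert kabsch_superpose(pre_rotated, b.coords).rmsd == pytest.approx(fwd, abs=1e-9)


def test_kabsch_matches_scipy_align_vectors_oracle():
    for seed in range(5):
        a, b = synth.make_coordinates(seed, n=10, noise_sd=0.5)
        pa = a.coords - a.coords.mean(axis=0)
        pb = b.coords - b.coords.mean(axis=0)
        # scipy's independent Kabsch solves target = R @ moving
        rot, rssd = Rotation.align_vectors(pb, pa)
        oracle_rmsd = rssd / np.sqrt(len(pa))
        ours = kabsch_superpose(a.coords, b.coords).rmsd
        assert ours == pytest.approx(oracle_rmsd, rel=1e-6)


def test_kabsch_matches_rotation_search_oracle():
    """Kabsch attains the optimum found by an independent numerical search
    over rotations (random multistart + Nelder–Mead on the rotation vector),
    and never loses to any sampled rotation."""
    from scipy.optimize import minimize

    a, b = synth.make_coordinates(3, n=10, noise_sd=0.5)
    pa = a.coords - a.coords.mean(axis=0)
    pb = b.coords - b.coords.mean(axis=0)

    def rmsd_of(rotvec):
        d = Rotation.from_rotvec(rotvec).apply(pa) - pb
        return float(np.sqrt(np.mean(np.sum(d**2, axis=1))))

    sample = Rotation.random(500, random_state=0)
    sampled = [rmsd_of(r.as_rotvec()) for r in sample]
    starts = np.argsort(sampled)[:5]
    best = min(
        minimize(rmsd_of, sample[int(i)].as_rotvec(), method="Nelder-Mead").fun
        for i in starts
    )
    ours = kabsch_superpose(a.coords, b.coords).rmsd
    assert ours <= min(sampled) + 1e-9
    assert ours == pytest.approx(best, rel=1e-4)


def test_noise_rmsd_near_sqrt3_sigma():
    sigma = 0.5
    rmsds = []
    for seed in range(5):
        a, b = synth.make_coordinates(seed, n=200, noise_sd=sigma)
        rmsds.append(superpose_sets(a, b).rmsd)
    expected = np.sqrt(3.0) * sigma
    assert 0.75 * expected <= np.mean(rmsds) <= 1.25 * expected


def test_rmsd_monotone_in_noise():
    means = []
    for sigma in (0.1, 0.5, 1.0):
        vals = [
            superpose_sets(*synth.make_coordinates(seed, n=150, noise_sd=sigma)).rmsd
            for seed in range(5)
        ]
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]


def test_collinear_points_rejected():
    line = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
    with pytest.raises(ValueError, match="collinear"):
        kabsch_superpose(line, line)
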