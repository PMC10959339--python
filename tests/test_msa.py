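import math

import numpy as np
import pytest

from qtykit import msa, stats, synth


def _aln(rows):
    return msa.Alignment(rows=tuple(rows), ids=tuple(f"s{i}" for i in range(len(rows))))


def test_read_alignment(tmp_path):
    p = tmp_path / "a.fasta"
    p.write_text(">a\nLLQQ\n>b\nllqq\n>c\nL-QQ\n")
    aln = msa.read_alignment(p)
    assert (aln.n_rows, aln.n_cols) == (3, 4)
    assert aln.rows[1] == "LLQQ"  # lowercase normalized


def test_ragged_alignment_rejected():
    with pytest.raises(ValueError, match="ragged"):
        _aln(["LLQ", "LLQQ"])


def test_pair_vectors_frequencies():
    aln = _aln(["LQ", "LQ", "LL", "QQ", "-Q"])
    x, y, kept = msa.pair_vectors(aln, ("L", "Q"), min_occupancy=0.5)
    assert kept == [0, 1]
    # col 0: 3 L, 1 Q of 4 non-gap; col 1: 1 L, 4 Q of 5
    assert x[0] == pytest.approx(0.75)
    assert y[0] == pytest.approx(0.25)
    assert x[1] == pytest.approx(0.2)
    assert y[1] == pytest.approx(0.8)


def test_pair_vectors_occupancy_filter():
    aln = _aln(["L---", "L-L-", "LQL-", "LQLL"])
    x, y, kept = msa.pair_vectors(aln, ("L", "Q"), min_occupancy=0.5)
    assert kept == [0, 1, 2]
    with pytest.raises(ValueError):
        msa.pair_vectors(_aln(["--", "--", "--"]), ("L", "Q"))


def test_pair_frequencies_sum_below_one():
    aln, _ = synth.make_msa(0, n_rows=30, n_cols=100, coupling=0.4)
    x, y, _ = msa.pair_vectors(aln, ("L", "Q"))
    assert np.all(x + y <= 1.0 + 1e-12)


def test_internal_conservation_closed_forms():
    invariant = _aln(["LL", "LL", "LL"])
    assert msa.internal_conservation(invariant).scores == (1.0, 1.0)
    two_state = _aln(["LQ"] * 10 + ["QL"] * 10)
    expected = 1.0 - math.log(2) / math.log(20)
    assert msa.internal_conservation(two_state).scores[0] == pytest.approx(expected)
    with_gap_col = _aln(["L-", "L-", "L-"])
    assert math.isnan(msa.internal_conservation(with_gap_col).scores[1])


def test_uniform_twenty_residue_column_has_zero_conservation():
    col = "ACDEFGHIKLMNPQRSTVWY"
    aln = _aln([c * 2 for c in col])
    assert msa.internal_conservation(aln).scores[0] == pytest.approx(0.0, abs=1e-12)


def test_column_filtering_order_independent():
    aln, cons = synth.make_msa(2, n_rows=20, n_cols=200, coupling=0.3)
    x, y, kept = msa.pair_vectors(aln, ("L", "Q"), min_occupancy=0.5)
    z_joint = [cons.scores[j] for j in kept]
    # subsetting conservation after the fact equals joint filtering
    z_sub = [cons.scores[j] for j in range(aln.n_cols) if j in set(kept)]
    assert z_joint == z_sub


def test_planted_negative_coupling_detected():
    negatives = 0
    for seed in range(20):
        aln, cons = synth.make_msa(seed, n_rows=40, n_cols=400, coupling=-0.5)
        res = msa.pair_correlation(aln, ("L", "Q"), conservation=cons, n_boot=200, seed=seed)
        if res.rho < 0:
            negatives += 1
    assert negatives >= 19  # >= 95% of seeds


def test_confounder_inflates_raw_correlation():
    """With zero true coupling and a strong shared conservation driver, the
    raw correlation is spuriously positive and partialing shrinks it."""
    shrunk = positive = 0
    for seed in range(20):
        aln, cons = synth.make_msa(
            seed, n_rows=40, n_cols=400, coupling=0.0, confounder_strength=0.8
        )
        res = msa.pair_correlation(aln, ("L", "Q"), conservation=cons, n_boot=200, seed=seed)
        if res.rho > 0:
            positive += 1
        if abs(res.partial_rho) < abs(res.rho):
            shrunk += 1
    assert positive >= 18
    assert shrunk >= 18  # >= 90% of seeds


def test_independent_conservation_leaves_partial_close_to_raw():
    diffs = []
    for seed in range(10):
        aln, _ = synth.make_msa(seed, n_rows=40, n_cols=500, coupling=0.5)
        rng = np.random.default_rng(seed + 1000)
        cons = msa.ConservationVector(
            scores=tuple(rng.uniform(size=aln.n_cols)), scale="INTERNAL_ENTROPY"
        )
        res = msa.pair_correlation(aln, ("L", "Q"), conservation=cons, n_boot=200, seed=seed)
        diffs.append(abs(res.partial_rho - res.rho))
    assert np.median(diffs) < 0.03


def test_constant_conservation_degenerate():
    aln, _ = synth.make_msa(3, n_rows=20, n_cols=100, coupling=0.3)
    cons = msa.ConservationVector(scores=tuple([0.5] * aln.n_cols), scale="INTERNAL_ENTROPY")
    with pytest.raises(ValueError):
        msa.pair_correlation(aln, ("L", "Q"), conservation=cons, n_boot=200, seed=0)


def test_bootstrap_ci_brackets_rho():
    aln, cons = synth.make_msa(4, n_rows=40, n_cols=300, coupling=0.6)
    res = msa.pair_correlation(aln, ("L", "Q"), conservation=cons, n_boot=300, seed=4)
    assert -1 <= res.ci_low <= res.rho <= res.ci_high <= 1
    assert res.n_bootstrap == 300


def test_consurf_grade_scale_validation():
    msa.ConservationVector(scores=(1.0, 9.0, 5.0), scale="CONSURF_GRADE_1_9")
    with pytest.raises(ValueError):
        msa.ConservationVector(scores=(0.0,), scale="CONSURF_GRADE_1_9")
    with pytest.raises(ValueError):
        msa.ConservationVector(scores=(1.5,), scale="INTERNAL_ENTROPY")
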