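import numpy as np
import pytest

from qtykit import mutlib, stats, synth
from qtykit.synth import make_toy_transporter


def test_library_arithmetic():
    residues = [("P", i, "L") for i in range(1, 862)]
    lib = mutlib.build_library(residues)
    assert len(lib.entries) == 16359
    assert lib.residue_set_size == 861


def test_single_residue_library():
    lib = mutlib.build_library([("P", 1, "A")])
    assert len(lib.entries) == 19
    assert all(alt != "A" for _, _, _, alt in lib.entries)
    assert len(set(lib.entries)) == 19


def test_empty_library():
    assert mutlib.build_library([]).entries == ()


def test_duplicate_residue_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        mutlib.build_library([("P", 1, "L"), ("P", 1, "L")])


def test_select_tm_hydrophobics_toy():
    from qtykit.topology import ProteinRecord, topology_from_rows

    prot = ProteinRecord("P", "p", "AALIVFAAA")
    topo = topology_from_rows([("TM_HELIX", 3, 9)], 9)
    residues = mutlib.select_tm_hydrophobics([prot], {"P": topo})
    assert [(pos, ref) for _, pos, ref in residues] == [(3, "L"), (4, "I"), (5, "V"), (6, "F")]


def test_select_tm_hydrophobics_no_tm():
    from qtykit.topology import ProteinRecord, topology_from_rows

    prot = ProteinRecord("P", "p", "LIVF")
    topo = topology_from_rows([("CYTOPLASMIC", 1, 4)], 4)
    assert mutlib.select_tm_hydrophobics([prot], {"P": topo}) == []


def test_forward_comparator_sets_are_the_fixed_ones():
    groups = mutlib.comparator_groups("L", "forward")
    assert groups["qty_target"] == {"Q"}
    assert groups["other_polar"] == set("DERKHNSTY")
    assert mutlib.comparator_groups("I", "forward")["other_polar"] == set("DERKHNSQY")
    assert mutlib.comparator_groups("F", "forward")["other_polar"] == set("DERKHNSTQ")


def test_reverse_comparator_sets():
    groups = mutlib.comparator_groups("Y", "reverse")
    assert groups["qty_target"] == {"F"}
    assert groups["other_nonpolar"] == set("ACGILMPWV")
    # T reverts to I only, never V
    assert mutlib.comparator_groups("T", "reverse")["qty_target"] == {"I"}


def test_comparator_groups_inapplicable_residue():
    with pytest.raises(ValueError):
        mutlib.comparator_groups("A", "forward")
    with pytest.raises(ValueError):
        mutlib.comparator_groups("L", "reverse")


def test_groups_are_disjoint_within_all19():
    for ref in "LIVF":
        g = mutlib.comparator_groups(ref, "forward")
        assert g["qty_target"].isdisjoint(g["other_polar"])
        assert g["qty_target"] <= g["all19"]
        assert g["other_polar"] <= g["all19"]
    for ref in "QTY":
        g = mutlib.comparator_groups(ref, "reverse")
        assert g["qty_target"].isdisjoint(g["other_nonpolar"])


def test_summarize_recovers_planted_medians():
    residues = [("P", i, "L") for i in range(1, 501)]
    lib = mutlib.build_library(residues)
    scores = synth.make_score_table(0, lib, qty_median=0.3, other_median=0.8)
    summaries = {g.group: g for g in mutlib.summarize_groups(lib, scores)}
    assert summaries["qty_target"].n == 500
    assert summaries["qty_target"].median == pytest.approx(0.3, abs=0.05)
    assert summaries["other_polar"].median == pytest.approx(0.8, abs=0.05)
    assert summaries["qty_target"].q1 <= summaries["qty_target"].median <= summaries["qty_target"].q3


def test_summarize_constant_and_single_entry():
    lib = mutlib.build_library([("P", 1, "L")])
    scores = mutlib.ScoreTable({e: 0.5 for e in lib.entries})
    for g in mutlib.summarize_groups(lib, scores):
        assert g.median == 0.5 and g.q1 == 0.5 and g.q3 == 0.5


def test_missing_scores_listed():
    lib = mutlib.build_library([("P", 1, "L")])
    scores = mutlib.ScoreTable()
    with pytest.raises(ValueError, match="unscored"):
        mutlib.summarize_groups(lib, scores)


def test_score_table_rejects_out_of_range():
    t = mutlib.ScoreTable()
    with pytest.raises(ValueError):
        t[("P", 1, "L", "Q")] = 1.2


def test_shapiro_gate_rejects_bimodal_scores():
    """Spiked near-0/near-1 score distributions fail normality at n~900,
    motivating median/IQR summaries."""
    residues = [("P", i, "L") for i in range(1, 48)]  # 47*19 = 893 scores
    lib = mutlib.build_library(residues)
    scores = synth.make_score_table(1, lib, qty_median=0.3, other_median=0.9,
                                    concentration=0.4)
    values = [scores[e] for e in lib.entries]
    res = stats.shapiro_wilk(values)
    assert res.n == 893
    assert res.p_value < 0.01


def test_planted_median_difference_sign_recovered():
    hits = 0
    residues = [("P", i, "L") for i in range(1, 201)]
    lib = mutlib.build_library(residues)
    for seed in range(50):
        scores = synth.make_score_table(seed, lib, qty_median=0.3, other_median=0.8)
        s = {g.group: g for g in mutlib.summarize_groups(lib, scores)}
        if s["other_polar"].median > s["qty_target"].median:
            hits += 1
    assert hits >= 48  # >= 95% of replicates


def test_score_generator_medians_equal_no_significant_difference():
    residues = [("P", i, "L") for i in range(1, 201)]
    lib = mutlib.build_library(residues)
    nonsig = 0
    for seed in range(20):
        scores = synth.make_score_table(seed, lib, qty_median=0.5, other_median=0.5)
        qty_vals = [scores[e] for e in lib.entries if e[3] == "Q"]
        other = [scores[e] for e in lib.entries if e[3] in set("DERKHNSTY")]
        rng = np.random.default_rng(seed)
        other_sub = rng.choice(other, size=len(qty_vals), replace=False)
        res = stats.wilcoxon_signed_rank(np.array(qty_vals), other_sub)
        if res.p_value > 0.01:
            nonsig += 1
    assert nonsig >= 19  # >= 95% of seeds
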