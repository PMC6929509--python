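"""Emission models: coding chains, site windows, length distributions."""

import itertools
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import tiny_config, random_model
from tiergene.emissions import (
    fit_coding_markov,
    fit_homogeneous_markov,
    fit_length_distribution,
    fit_site_window,
    score_segment,
)
from tiergene.genes import revcomp
from tiergene.model import uniform_model


def brute_coding_tally(seqs_with_cp, k, order, cp, ctx, base):
    """Independent add-one conditional probability by direct counting."""
    num = 0
    den = {b: 0 for b in "ACGT"}
    for seq, cp0 in seqs_with_cp:
        for t in range(len(seq)):
            if t < order:
                continue
            if (cp0 + t) % 3 != cp or seq[t - order : t] != ctx:
                continue
            den[seq[t]] += 1
    tot = sum(den.values())
    return (den[base] + 1) / (tot + 4)


def test_fit_coding_markov_matches_hand_tally():
    data = [("AAAC", 0)]
    m = fit_coding_markov(data, k=0)
    for cp in range(3):
        for b in "ACGT":
            want = brute_coding_tally(data, 0, 0, cp, "", b)
            got = math.exp(m.tables[0][cp, 0, "ACGT".index(b)])
            assert got == pytest.approx(want, abs=1e-12), (cp, b)


def test_fit_coding_markov_alternating_first_order():
    m = fit_coding_markov([("ACACAC", 0)], k=1)
    data = [("ACACAC", 0)]
    for cp, ctx, b in [(1, "A", "C"), (2, "C", "A"), (2, "A", "C"), (0, "C", "A")]:
        want = brute_coding_tally(data, 1, 1, cp, ctx, b)
        got = math.exp(m.tables[1][cp, "ACGT".index(ctx), "ACGT".index(b)])
        assert got == pytest.approx(want, abs=1e-12)
    # the observed successor is the modal base of its conditional
    assert int(np.argmax(m.tables[1][1, 0])) == "ACGT".index("C")


def test_fitted_model_beats_mismatched_model_on_own_data():
    """Likelihood of a sequence under a model fitted to many copies of it
    exceeds the likelihood under a model fitted to a different sequence."""
    rng = np.random.default_rng(5)
    for _ in range(10):
        a = "".join(rng.choice(list("ACGT"), size=30))
        b = "".join(rng.choice(list("ACGT"), size=30))
        if a == b:
            continue
        ma = fit_coding_markov([(a, 0)] * 50, k=1)
        mb = fit_coding_markov([(b, 0)] * 50, k=1)
        assert ma.score(a, 0) >= mb.score(a, 0)


def test_length_distribution_point_mass_and_errors():
    ld = fit_length_distribution([10, 10, 10], max_len=20, smoothing_bandwidth=0)
    assert ld.pmf()[9] == pytest.approx(1.0)
    assert ld.logp(9) == float("-inf")
    with pytest.raises(ValueError):
        fit_length_distribution([], max_len=10)
    with pytest.raises(ValueError):
        fit_length_distribution([0, 3], max_len=10)
    with pytest.warns(UserWarning):
        fit_length_distribution([5, 50], max_len=10, smoothing_bandwidth=0)


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(st.integers(1, 80), min_size=1, max_size=30),
    st.integers(0, 12),
)
def test_length_distribution_normalized_and_mean_near_empirical(lengths, bw):
    ld = fit_length_distribution(lengths, max_len=100, smoothing_bandwidth=bw)
    assert ld.pmf().sum() == pytest.approx(1.0, abs=1e-9)
    emp = float(np.mean(lengths))
    # smoothing shifts mass by at most the kernel radius (plus edge effects)
    assert abs(ld.mean() - emp) <= bw + 1.0


def test_site_window_consensus_is_hard():
    m = fit_site_window(["GTAAG", "GTGAG"], width=5, consensus={0: "G", 1: "T"})
    assert m.score("GTAAG") > float("-inf")
    assert m.score("GCAAG") == float("-inf")
    with pytest.raises(ValueError):
        m.score("GTA")


def test_score_segment_ir_uniform():
    cfg = tiny_config()
    model = uniform_model(cfg)
    ir = model.state_set["IR"]
    assert score_segment(ir, "A", model) == pytest.approx(math.log(0.25))
    assert score_segment(ir, "ACGT", model) == pytest.approx(4 * math.log(0.25))


def test_score_segment_donor_without_gt_is_impossible():
    cfg = tiny_config()
    model = uniform_model(cfg)
    dss = model.state_set["DSS_0"]
    assert score_segment(dss, "GC", model) == float("-inf")
    assert score_segment(dss, "GT", model) > float("-inf")


def test_exon_score_equals_explicit_position_product():
    """Segment score minus the length term equals a direct per-position
    table-lookup product computed independently here."""
    rng = np.random.default_rng(3)
    cfg = tiny_config(k=1, max_exon_len=30)
    model = random_model(rng, cfg)
    st_int = model.state_set["E_int_1_M"]
    cm = model.coding_model("exon_internal", "medium")
    for _ in range(20):
        L = 9  # entry phase 1 + 9 = exit phase 1
        seq = "".join(rng.choice(list("ACGT"), size=L))
        # avoid hard-constraint rejections in the comparison
        got = score_segment(st_int, seq, model, entry_phase=1, context="A",
                            enforce_constraints=False)
        want = model.length_distribution("exon_internal", "medium").logp(L)
        prev = "A"
        for t, b in enumerate(seq):
            cp = (1 + t) % 3
            want += cm.tables[1][cp, "ACGT".index(prev), "ACGT".index(b)]
            prev = b
        assert got == pytest.approx(want, abs=1e-9)


def test_reverse_exon_scores_reverse_complement():
    rng = np.random.default_rng(4)
    cfg = tiny_config(k=1, max_exon_len=30)
    model = random_model(rng, cfg)
    fwd = model.state_set["E_int_2_M"]
    rev = model.state_set["rE_int_1_M"]  # entry transcript phase 1, exit 2 at l=7
    seq = "ACGTTGC"  # length 7: fwd entry 1 -> exit (1+7)%3 = 2
    f = score_segment(fwd, seq, model, entry_phase=1, context="", enforce_constraints=False)
    r = score_segment(rev, revcomp(seq), model, entry_phase=2, context="", enforce_constraints=False)
    assert f == pytest.approx(r, abs=1e-9)


@pytest.mark.parametrize("k,length", [(0, 3), (1, 4), (1, 5)])
def test_unconstrained_emission_sums_to_one(k, length):
    """Summing the (length-term-free) emission over all 4^l sequences gives 1."""
    rng = np.random.default_rng(11)
    cfg = tiny_config(k=k, k_noncoding=k, max_exon_len=12)
    model = random_model(rng, cfg)
    st_int = model.state_set["E_int_0_M"]
    entry = (0 - length) % 3
    lterm = model.length_distribution("exon_internal", "medium").logp(length)
    total = 0.0
    for tup in itertools.product("ACGT", repeat=length):
        s = "".join(tup)
        total += math.exp(
            score_segment(st_int, s, model, entry_phase=entry, context="", enforce_constraints=False)
            - lterm
        )
    assert total == pytest.approx(1.0, abs=1e-9)
    # intergenic chain likewise
    total_ir = sum(
        math.exp(score_segment(model.state_set["IR"], "".join(t), model))
        for t in itertools.product("ACGT", repeat=3)
    )
    assert total_ir == pytest.approx(1.0, abs=1e-9)


def test_constrained_emission_mass_is_deficient():
    """Hard ATG/stop constraints remove probability mass from exon states."""
    rng = np.random.default_rng(12)
    cfg = tiny_config(k=0)
    model = random_model(rng, cfg)
    st_sing = model.state_set["E_single_H"]
    lterm = model.length_distribution("exon_single", "high").logp(6)
    total = 0.0
    for tup in itertools.product("ACGT", repeat=6):
        s = "".join(tup)
        v = score_segment(st_sing, s, model, context="")
        if v > float("-inf"):
            total += math.exp(v - lterm)
    assert 0.0 < total < 1.0


def test_empty_training_set_warns_and_is_uniform():
    with pytest.warns(UserWarning):
        m = fit_coding_markov([], k=1)
    assert m.score("ACG", 0) == pytest.approx(3 * math.log(0.25))
    with pytest.warns(UserWarning):
        hm = fit_homogeneous_markov([], k=1)
    assert hm.score("ACG") == pytest.approx(3 * math.log(0.25))
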