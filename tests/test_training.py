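"""Training: labelling, transition counting/estimation, strategies, CV."""

import warnings

import numpy as np
import pytest

from oracles import tiny_config
from tiergene.genes import GeneStructure, revcomp
from tiergene.model import ModelConfig, TransitionMatrix
from tiergene.states import build_state_set, build_topology, collapse_map
from tiergene.synth import SynthConfig, generate_corpus
from tiergene.training import (
    TrainingCorpus,
    count_transitions,
    cutoff_coverage_report,
    estimate_transitions_mle,
    kfold_cross_validate,
    label_training_exons,
    split_transitions_equally,
    train_model,
)


def _mini_cfg(**kw):
    # small windows so hand-built genes stay compact
    base = dict(k=1, k_noncoding=1, d=4, max_exon_len=60, dss_window=2, ass_window=2,
                low_t=0.40, high_t=0.60, length_bandwidth=0)
    base.update(kw)
    return ModelConfig(**base)


def _two_exon_gene(gc_first_high=True):
    """Forward two-exon gene: exon GCs ~0.83 and ~0.17."""
    exon1 = "ATGGGCGGC"  # GC 7/9
    exon2 = "ATTTAATAA"  # wait: needs no internal stop; use below
    exon2 = "ATAATTTAA"  # codons (entry phase 0): ATA ATT TAA -> ends with stop
    intron = "GT" + "CA" + "AG"  # interior 2 <= d
    seq = "A" * 10 + exon1 + intron + exon2 + "A" * 10
    gene = GeneStructure("g1", "r1", "forward", [(10, 19), (25, 34)])
    return seq, gene


def test_label_two_exon_gradient_gene():
    cfg = _mini_cfg()
    seq, gene = _two_exon_gene()
    corpus = TrainingCorpus({"r1": seq}, {"r1": [gene]})
    lab = label_training_exons(corpus, cfg)
    assert not lab.skipped
    rec = lab.records["r1"][0]
    # initial exon GC 7/9 > highT -> high tier; length 9 -> phase 0
    assert rec.path[0] == "E_init_0_H"
    # terminal exon GC 1/9 < lowT -> low tier
    assert rec.path[-1] == "E_term_L"
    assert rec.gene.exon_labels[0] == ("exon_initial", 0, "high")
    assert rec.gene.exon_labels[1] == ("exon_terminal", None, "low")


def test_initial_exon_phase_is_cumulative_length_mod_three():
    cfg = _mini_cfg()
    # initial exon of length 7 -> exponent 1; internal exon keeps the walk
    exon1 = "ATGGGGG"          # 7 nt, exit phase 1
    exon2 = "CCCCCCCCC"        # 9 nt internal, exit phase stays 1
    exon3 = "CATAA"            # 5 nt: (1 + 5) % 3 == 0, ends TAA
    i1 = "GTCAAG"
    i2 = "GTTTAG"
    seq = "A" * 8 + exon1 + i1 + exon2 + i2 + exon3 + "A" * 8
    s1 = 8
    e1 = s1 + 7
    s2 = e1 + 6
    e2 = s2 + 9
    s3 = e2 + 6
    gene = GeneStructure("g", "r", "forward", [(s1, e1), (s2, e2), (s3, s3 + 5)])
    corpus = TrainingCorpus({"r": seq}, {"r": [gene]})
    lab = label_training_exons(corpus, cfg)
    assert not lab.skipped, lab.skipped
    rec = lab.records["r"][0]
    # independent codon walk: phases are cumulative coding length mod 3
    cum = np.cumsum([7, 9, 5]) % 3
    assert rec.path[0].startswith(f"E_init_{cum[0]}")
    assert rec.path[1] == f"DSS_{cum[0]}"
    assert any(p.startswith(f"E_int_{cum[1]}") for p in rec.path)


def test_count_transitions_hand_tally():
    cfg = _mini_cfg()
    seq, gene = _two_exon_gene()
    corpus = TrainingCorpus({"r1": seq}, {"r1": [gene]})
    lab = label_training_exons(corpus, cfg)
    ss = build_state_set()
    counts = count_transitions(lab, ss)
    assert counts.count("IR", "E_init_0_H") == 1
    assert counts.count("DSS_0", "I_short_0") == 1  # interior 2 <= d=4
    assert counts.count("I_short_0", "ASS_0") == 1
    assert counts.count("ASS_0", "E_term_L") == 1
    assert counts.count("E_term_L", "IR") == 1
    # conservation: one gene -> one gene-start transition out of IR
    ir = ss.ordinal("IR")
    row = counts.A[ir].copy()
    row[ir] = 0
    assert row.sum() == 1
    # intergenic self loops: 20 IR bases in 2 runs
    assert counts.A[ir, ir] == 18


def test_count_transitions_reverse_gene_mirrors_forward():
    cfg = _mini_cfg()
    seq, gene = _two_exon_gene()
    rseq = revcomp(seq)
    L = len(seq)
    rexons = sorted((L - e, L - s) for (s, e) in gene.exons)
    rgene = GeneStructure("g1", "r1", "reverse", rexons)
    lab = label_training_exons(TrainingCorpus({"r1": rseq}, {"r1": [rgene]}), cfg)
    counts = count_transitions(lab, build_state_set())
    assert counts.count("IR", "rE_term_0_L") == 1
    assert counts.count("rASS_0", "rI_short_0") == 1
    assert counts.count("rDSS_0", "rE_init_H") == 1
    assert counts.count("rE_init_H", "IR") == 1


def test_mle_estimator_matches_count_ratios():
    rng = np.random.default_rng(8)
    ss = build_state_set()
    support = build_topology(ss)
    from tiergene.training import TransitionCounts

    A = np.zeros((len(ss), len(ss)))
    for (a, b) in support:
        A[ss.ordinal(a), ss.ordinal(b)] = rng.integers(0, 50)
    counts = TransitionCounts(ss, A, r=1.0)
    tm = estimate_transitions_mle(counts)
    # brute-force oracle, edge by edge
    rows = {}
    for (a, b) in support:
        rows.setdefault(a, []).append(b)
    for a, outs in rows.items():
        tot = sum(A[ss.ordinal(a), ss.ordinal(b)] + 1.0 for b in outs)
        for b in outs:
            want = (A[ss.ordinal(a), ss.ordinal(b)] + 1.0) / tot
            assert tm.p(a, b) == pytest.approx(want, abs=1e-12)


def test_mle_all_zero_counts_gives_uniform_rows():
    ss = build_state_set()
    from tiergene.training import TransitionCounts

    counts = TransitionCounts(ss, np.zeros((len(ss), len(ss))), r=1.0)
    tm = estimate_transitions_mle(counts)
    outs = [b for (a, b) in build_topology(ss) if a == "ASS_0"]
    for b in outs:
        assert tm.p("ASS_0", b) == pytest.approx(1.0 / len(outs))


def _random_collapsed_matrix(rng) -> TransitionMatrix:
    ss = build_state_set(tiered=False)
    probs = np.zeros((len(ss), len(ss)))
    rows = {}
    for (a, b) in build_topology(ss):
        rows.setdefault(a, []).append(b)
    for a, outs in rows.items():
        w = rng.random(len(outs)) + 1e-3
        w /= w.sum()
        for b, p in zip(outs, w):
            probs[ss.ordinal(a), ss.ordinal(b)] = p
    return TransitionMatrix(ss, probs)


def test_split_transitions_equally_thirds_and_row_sums():
    rng = np.random.default_rng(0)
    base = _random_collapsed_matrix(rng)
    split = split_transitions_equally(base)
    assert split.p("ASS_0", "E_int_1_H") == pytest.approx(base.p("ASS_0", "E_int_1") / 3)
    assert split.p("ASS_0", "E_int_1_M") == split.p("ASS_0", "E_int_1_L")
    rows = split.probs.sum(axis=1)
    assert np.allclose(rows[rows > 0], 1.0, atol=1e-9)
    with pytest.raises(ValueError):
        split_transitions_equally(split)


def test_equal_strategy_gives_equal_tier_triples(small_corpus, bench_cfg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = train_model(small_corpus, bench_cfg, strategy="equal")
    tm = model.transitions
    for x in range(3):
        for y in range(3):
            vals = {tm.p(f"ASS_{x}", f"E_int_{y}_{t}") for t in "HML"}
            assert len(vals) == 1


def test_training_is_deterministic(small_corpus, bench_cfg, tmp_path):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m1 = train_model(small_corpus, bench_cfg)
        m2 = train_model(small_corpus, bench_cfg)
    p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
    m1.save(p1)
    m2.save(p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_invalid_genes_are_skipped_with_reasons():
    cfg = _mini_cfg()
    seq, good = _two_exon_gene()
    broken = GeneStructure("g2", "r1", "forward", [(11, 19)])  # no ATG, bad frame
    corpus = TrainingCorpus({"r1": seq}, {"r1": [good]})
    corpus2 = TrainingCorpus({"r1": seq}, {"r1": [broken]})
    with pytest.warns(UserWarning):
        lab = label_training_exons(corpus2, cfg)
    assert len(lab.skipped) == 1 and lab.skipped[0][0] == "g2"
    with pytest.raises(ValueError):
        train_model(corpus2, cfg)


def test_cutoff_coverage_report_flags_unseen_tiers():
    cfg = _mini_cfg()
    seq, gene = _two_exon_gene()  # only high and low exon tiers observed
    lab = label_training_exons(TrainingCorpus({"r1": seq}, {"r1": [gene]}), cfg)
    counts = count_transitions(lab, build_state_set())
    uncovered = cutoff_coverage_report(counts, threshold=1)
    into_medium = [e for e in uncovered if e[1].endswith("_M")]
    all_medium_edges = [
        (a, b) for (a, b) in build_topology(build_state_set()) if b.endswith("_M")
    ]
    assert len(into_medium) == len(all_medium_edges)
    # at threshold 1 the report is exactly the unobserved support edges,
    # so it is empty if and only if training covered every transition
    zero_edges = [
        (a, b)
        for (a, b) in build_topology(build_state_set())
        if counts.count(a, b) == 0
    ]
    assert sorted(e[:2] for e in uncovered) == sorted(zero_edges)


def test_kfold_partition_and_determinism(bench_cfg):
    corpus = generate_corpus(SynthConfig(seed=21, n_regions=4, region_length=2500, genes_per_region=(1, 1)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r1 = kfold_cross_validate(corpus, bench_cfg, folds=2, seed=5)
        r2 = kfold_cross_validate(corpus, bench_cfg, folds=2, seed=5)
    assert (r1.best_low_t, r1.best_high_t) == (bench_cfg.low_t, bench_cfg.high_t)
    info1 = r1.per_cutoff[(bench_cfg.low_t, bench_cfg.high_t)]
    info2 = r2.per_cutoff[(bench_cfg.low_t, bench_cfg.high_t)]
    assert info1["score"] == info2["score"]  # same seed, same partition
    assert len(info1["folds"]) == 2
    with pytest.raises(ValueError):
        kfold_cross_validate(corpus, bench_cfg, folds=10, seed=1)
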