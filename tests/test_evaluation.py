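"""Base/exon/gene-level evaluation and GC-variability metrics."""

import math

import numpy as np
import pytest

from tiergene.evaluation import compare_tools, evaluate, gc_distance, gene_gc_sd
from tiergene.genes import GeneStructure


def _gene(gid, exons, strand="forward", seqid="s"):
    return GeneStructure(gid, seqid, strand, exons)


def test_truth_against_itself_is_perfect(medium_corpus):
    truth = [g for gs in medium_corpus.annotations.values() for g in gs]
    rep = evaluate(truth, truth)
    for level in ("base", "exon", "gene"):
        c = getattr(rep, level)
        assert c.fp == 0 and c.fn == 0
        assert c.sen == 1.0 and c.spe == 1.0


def test_exact_prediction_counts():
    truth = [_gene("t", [(10, 50), (100, 150)])]
    pred = [_gene("p", [(10, 50), (100, 150)])]
    rep = evaluate(pred, truth)
    assert (rep.gene.tp, rep.exon.tp, rep.exon.fp) == (1, 2, 0)


def test_extra_exon_breaks_gene_level_only():
    truth = [_gene("t", [(10, 50), (100, 150)])]
    pred = [_gene("p", [(10, 50), (100, 150), (200, 230)])]
    rep = evaluate(pred, truth)
    assert (rep.exon.tp, rep.exon.fp) == (2, 1)
    assert rep.gene.tp == 0 and rep.gene.fp == 1


def test_shifted_exon_fails_exon_level_but_overlaps_bases():
    truth = [_gene("t", [(10, 50)])]
    pred = [_gene("p", [(11, 51)])]
    rep = evaluate(pred, truth)
    assert rep.exon.tp == 0
    assert rep.base.tp == 39  # overlap of [10,50) and [11,51)
    assert rep.base.fp == 1 and rep.base.fn == 1


def test_base_level_is_strand_aware():
    truth = [_gene("t", [(10, 50)], strand="forward")]
    pred = [_gene("p", [(10, 50)], strand="reverse")]
    rep = evaluate(pred, truth)
    assert rep.base.tp == 0 and rep.base.fp == 40 and rep.base.fn == 40


def test_base_conservation():
    truth = [_gene("t1", [(0, 30), (50, 80)]), _gene("t2", [(100, 160)], strand="reverse")]
    pred = [_gene("p1", [(10, 40)]), _gene("p2", [(100, 130)], strand="reverse")]
    rep = evaluate(pred, truth)
    assert rep.base.tp + rep.base.fn == 30 + 30 + 60
    assert rep.base.tp + rep.base.fp == 30 + 30


def test_undefined_ratios_are_nan_not_zero():
    rep = evaluate([], [_gene("t", [(0, 9)])])
    assert math.isnan(rep.base.spe) and math.isnan(rep.gene.spe)
    assert rep.base.sen == 0.0


def test_gc_distance_values_and_pairwise_oracle():
    seq = "G" * 30 + "A" * 10 + "GCGCA" * 6 + "T" * 30
    gene = _gene("g", [(0, 10), (30, 40), (45, 55)])
    profile_dist = gc_distance(gene, seq)
    from tiergene.gc import gene_gc_profile

    prof = gene_gc_profile(gene, seq)
    brute = max(abs(a - b) for a in prof for b in prof)
    assert profile_dist == pytest.approx(brute)
    assert gc_distance(_gene("s", [(0, 10)]), seq) == 0.0


@pytest.mark.parametrize(
    "seqs,expected",
    [(["GCGC", "GCGC"], 0.0), (["AAAA", "GGGG"], 0.5)],
)
def test_gene_gc_sd_known_values(seqs, expected):
    seq = "TT".join(seqs)
    exons = []
    pos = 0
    for s in seqs:
        exons.append((pos, pos + len(s)))
        pos += len(s) + 2
    assert gene_gc_sd(_gene("g", exons), seq) == pytest.approx(expected)


def test_gene_gc_sd_matches_two_pass_oracle():
    rng = np.random.default_rng(2)
    for _ in range(10):
        n = int(rng.integers(2, 6))
        seqs = ["".join(rng.choice(list("ACGT"), size=20)) for _ in range(n)]
        seq = "TTTT".join(seqs)
        exons = [(i * 24, i * 24 + 20) for i in range(n)]
        prof = [s.count("G") / 20 + s.count("C") / 20 for s in seqs]
        mean = sum(prof) / n
        want = math.sqrt(sum((p - mean) ** 2 for p in prof) / n)
        assert gene_gc_sd(_gene("g", exons), seq) == pytest.approx(want, abs=1e-12)


def test_compare_tools_partitions_and_conservation():
    seq = {"s": "GCGCGCGCGC" + "ATATATATAT" + "GCATGCATGC" * 10}
    truth = [_gene("t1", [(0, 10)]), _gene("t2", [(10, 20)]), _gene("t3", [(20, 30)])]
    preds_a = [_gene("a1", [(0, 10)]), _gene("a2", [(10, 20)])]
    preds_b = [_gene("b1", [(10, 20)]), _gene("b2", [(20, 30)])]
    comp = compare_tools(preds_a, preds_b, truth, seq)
    assert [g.gene_id for g in comp.unique_to_a] == ["t1"]
    assert [g.gene_id for g in comp.unique_to_b] == ["t3"]
    assert [g.gene_id for g in comp.common] == ["t2"]
    correct_a = {"t1", "t2"}
    assert len(comp.unique_to_a) + len(comp.common) == len(correct_a)
    same = compare_tools(preds_a, preds_a, truth, seq)
    assert not same.unique_to_a and not same.unique_to_b
    assert math.isnan(same.mean_sd["unique_to_a"])
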