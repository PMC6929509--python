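"""Viterbi decoding: optimality, structure extraction, re-scoring, symmetry."""

import math
import warnings

import numpy as np
import pytest

from oracles import best_parse_by_enumeration, plant_gene, random_dna, random_model, tiny_config
from tiergene.decoder import Parse, Segment, path_to_genes, score_fixed_path, viterbi_decode
from tiergene.genes import revcomp, validate_gene
from tiergene.model import mirror_model, uniform_model


def test_sequence_without_atg_decodes_all_intergenic():
    rng = np.random.default_rng(1)
    model = random_model(rng, tiny_config())
    seq = "CCGGCCGGCCGGCCGGCCGG"  # no ATG on either strand (revcomp = CCGG...)
    parse = viterbi_decode(seq, model)
    assert [s.state for s in parse.segments] == ["IR"]
    assert parse.tiles(len(seq))


def test_all_intergenic_score_closed_form():
    cfg = tiny_config()
    model = uniform_model(cfg)  # uniform emissions: every base log(1/4)
    seq = "CCGGCCGG"
    parse = viterbi_decode(seq, model)
    L = len(seq)
    p_stay = model.transitions.p("IR", "IR")
    want = L * math.log(0.25) + (L - 1) * math.log(p_stay)
    assert parse.total_log_prob == pytest.approx(want, abs=1e-9)
    assert score_fixed_path(seq, parse, model) == pytest.approx(want, abs=1e-9)


def test_viterbi_equals_exhaustive_enumeration_on_small_instances():
    """DP optimality against an independent brute-force parse enumerator."""
    rng = np.random.default_rng(7)
    cfg = tiny_config()
    for case in range(40):
        model = random_model(rng, cfg)
        seq = plant_gene(rng) if case % 3 == 0 else random_dna(rng, int(rng.integers(15, 31)))
        parse = viterbi_decode(seq, model)
        best, n_parses = best_parse_by_enumeration(seq, model)
        assert parse.total_log_prob == pytest.approx(best, abs=1e-9), (case, seq)
        # and the DP's own parse re-scores to the same value
        assert score_fixed_path(seq, parse, model) == pytest.approx(parse.total_log_prob, abs=1e-6)


def test_rescorer_never_exceeds_viterbi():
    rng = np.random.default_rng(19)
    cfg = tiny_config()
    model = random_model(rng, cfg)
    seq = plant_gene(rng)
    parse = viterbi_decode(seq, model)
    from oracles import enumerate_parses

    for alt in enumerate_parses(seq, model):
        assert score_fixed_path(seq, alt, model) <= parse.total_log_prob + 1e-9


def test_parse_segments_tile_and_sum(trained_model, medium_corpus):
    sid = medium_corpus.region_ids()[0]
    seq = medium_corpus.sequences[sid]
    parse = viterbi_decode(seq, trained_model)
    assert parse.tiles(len(seq))
    rescored = score_fixed_path(seq, parse, trained_model)
    assert rescored == pytest.approx(parse.total_log_prob, abs=1e-6)


def test_planted_gene_recovered_from_own_model(trained_model, medium_corpus):
    """Genes generated at strong emission contrast are recovered exactly
    when decoding with a model trained on the same generator."""
    hits, total = 0, 0
    for sid in medium_corpus.region_ids()[:4]:
        seq = medium_corpus.sequences[sid]
        preds = path_to_genes(viterbi_decode(seq, trained_model), seqid=sid)
        truth = medium_corpus.annotations[sid]
        total += len(truth)
        truth_keys = {(tuple(g.exons), g.strand) for g in truth}
        hits += sum(1 for g in preds if (tuple(g.exons), g.strand) in truth_keys)
    assert total >= 6
    assert hits / total >= 0.5


def test_predicted_genes_pass_structural_validation(trained_model, medium_corpus):
    cfg = trained_model.config
    for sid in medium_corpus.region_ids()[:4]:
        seq = medium_corpus.sequences[sid]
        for gene in path_to_genes(viterbi_decode(seq, trained_model), seqid=sid):
            assert validate_gene(gene, seq, min_intron=cfg.min_intron_len) == []
            assert gene.coding_length() % 3 == 0
            for (cat, phase, tier) in gene.exon_labels:
                assert tier in ("high", "medium", "low")


def test_path_to_genes_structures():
    assert path_to_genes(Parse([Segment("IR", 0, 50, 0.0)], 0.0)) == []
    parse = Parse(
        [Segment("IR", 0, 10, 0.0), Segment("E_single_M", 10, 19, 0.0), Segment("IR", 19, 30, 0.0)],
        0.0,
    )
    genes = path_to_genes(parse, seqid="chr")
    assert len(genes) == 1
    g = genes[0]
    assert g.strand == "forward" and g.exons == [(10, 19)]
    assert g.exon_labels == [("exon_single", None, "medium")]


def test_path_to_genes_rejects_malformed_runs():
    bad = Parse(
        [Segment("IR", 0, 5, 0.0), Segment("E_init_0_H", 5, 14, 0.0),
         Segment("rE_init_H", 20, 29, 0.0), Segment("IR", 29, 40, 0.0)],
        0.0,
    )
    with pytest.raises(ValueError):
        path_to_genes(bad)


def test_score_fixed_path_illegal_adjacency_is_minus_inf():
    cfg = tiny_config()
    model = uniform_model(cfg)
    seq = "C" * 10
    parse = Parse([Segment("IR", 0, 4, 0.0), Segment("ASS_0", 4, 6, 0.0), Segment("IR", 6, 10, 0.0)], 0.0)
    assert score_fixed_path(seq, parse, model) == float("-inf")


def test_decoding_handles_ambiguous_bases(trained_model):
    seq = "ACGTN" * 40 + "N" * 20
    parse = viterbi_decode(seq, trained_model)
    assert parse.tiles(len(seq))
    assert np.isfinite(parse.total_log_prob)


def test_strand_symmetry_exact(trained_model, medium_corpus):
    mirrored = mirror_model(trained_model)
    rows = mirrored.transitions.probs.sum(axis=1)
    assert np.allclose(rows[rows > 0], 1.0, atol=1e-9)
    for sid in medium_corpus.region_ids()[:3]:
        seq = medium_corpus.sequences[sid]
        p_f = viterbi_decode(seq, trained_model)
        p_r = viterbi_decode(revcomp(seq), mirrored)
        assert p_r.total_log_prob == pytest.approx(p_f.total_log_prob, abs=1e-9)
        L = len(seq)
        genes_f = {(tuple(g.exons), g.strand) for g in path_to_genes(p_f)}
        genes_r = {
            (tuple(sorted((L - e, L - s) for (s, e) in g.exons)),
             "forward" if g.strand == "reverse" else "reverse")
            for g in path_to_genes(p_r)
        }
        assert genes_f == genes_r
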