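"""Synthetic-genome generator: determinism, GC control, structural validity."""

import numpy as np
import pytest

from tiergene.gc import gene_gc_profile
from tiergene.genes import validate_gene
from tiergene.model import ModelConfig
from tiergene.synth import SynthConfig, corpus_stats, generate_corpus, generate_from_model
from tiergene.io import read_gff3, write_gff3


def _flat(seed, mode, n_regions=20, **kw):
    weights = {m: 0.0 for m in ("negative_gradient", "flat_high", "flat_medium", "flat_low")}
    weights[mode] = 1.0
    return SynthConfig(seed=seed, n_regions=n_regions, region_length=4000,
                       genes_per_region=(2, 2), mode_weights=weights, **kw)


def test_same_seed_reproduces_bytes():
    c1 = generate_corpus(SynthConfig(seed=9, n_regions=4, region_length=3000))
    c2 = generate_corpus(SynthConfig(seed=9, n_regions=4, region_length=3000))
    assert c1.sequences == c2.sequences
    k1 = [(g.seqid, g.strand, tuple(g.exons)) for gs in c1.annotations.values() for g in gs]
    k2 = [(g.seqid, g.strand, tuple(g.exons)) for gs in c2.annotations.values() for g in gs]
    assert k1 == k2
    c3 = generate_corpus(SynthConfig(seed=10, n_regions=4, region_length=3000))
    assert c3.sequences != c1.sequences


def test_every_generated_gene_is_structurally_valid():
    cfg = ModelConfig(low_t=0.45, high_t=0.60)
    corpus = generate_corpus(SynthConfig(seed=13, n_regions=25, region_length=4000, genes_per_region=(2, 2)))
    n = 0
    for sid, genes in corpus.annotations.items():
        for g in genes:
            assert validate_gene(g, corpus.sequences[sid], min_intron=cfg.min_intron_len) == [], g.gene_id
            n += 1
    assert n >= 40


def test_gradient_profiles_fall_and_span():
    corpus = generate_corpus(_flat(17, "negative_gradient"))
    checked = 0
    for sid, genes in corpus.annotations.items():
        for g in genes:
            prof = gene_gc_profile(g, corpus.sequences[sid])
            assert len(prof) >= 2
            for a, b in zip(prof, prof[1:]):
                assert b <= a + 0.04  # non-increasing within realization tolerance
            assert max(prof) - min(prof) >= 0.25
            checked += 1
    assert checked >= 30


def test_realized_exon_gc_within_tolerance_of_target():
    corpus = generate_corpus(_flat(23, "flat_medium", n_regions=70))
    gcs = []
    for sid, genes in corpus.annotations.items():
        for g in genes:
            gcs.extend(gene_gc_profile(g, corpus.sequences[sid]))
    assert len(gcs) >= 500
    assert max(abs(x - 0.50) for x in gcs) <= 0.03


def test_corpus_stats_conservation_and_contrast():
    grad = generate_corpus(_flat(29, "negative_gradient"))
    flat = generate_corpus(_flat(29, "flat_medium"))
    sg, sf = corpus_stats(grad), corpus_stats(flat)
    assert sum(sg["exon_gc_hist"][0]) == sg["n_exons"]
    assert sg["mean_gc_distance"] > sf["mean_gc_distance"]
    # flat-medium corpus concentrates in the medium band
    assert np.mean([0.45 <= x <= 0.55 for x in sf["exon_gc"]]) > 0.95


def test_truth_survives_gff3_round_trip(tmp_path):
    corpus = generate_corpus(SynthConfig(seed=3, n_regions=5, region_length=3000))
    genes = [g for gs in corpus.annotations.values() for g in gs]
    p = tmp_path / "truth.gff3"
    write_gff3(genes, p)
    back = read_gff3(p)
    assert sorted((g.seqid, g.strand, tuple(g.exons)) for g in back) == sorted(
        (g.seqid, g.strand, tuple(g.exons)) for g in genes
    )


def test_generate_from_model_valid_and_deterministic(trained_model):
    c1 = generate_from_model(trained_model, n_genes=24, seed=99)
    c2 = generate_from_model(trained_model, n_genes=24, seed=99)
    assert c1.sequences == c2.sequences
    assert c1.n_genes == 24
    cfg = trained_model.config
    for sid, genes in c1.annotations.items():
        for g in genes:
            assert validate_gene(g, c1.sequences[sid], min_intron=cfg.min_intron_len) == []


def test_infeasible_config_raises():
    with pytest.raises(Exception):
        generate_corpus(SynthConfig(seed=1, n_regions=1, region_length=300,
                                    genes_per_region=(3, 3)))
    with pytest.raises(ValueError):
        SynthConfig(seed=1, gradient_start=1.2)
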