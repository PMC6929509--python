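"""Three-level evaluation of gene predictions and GC-variability metrics.

Sensitivity = TP/(TP+FN) and specificity = TP/(TP+FP) are computed at the
nucleotide (coding base), exon and gene level.  The forward and reverse
strands are treated as different sequences for base-level counting.  An
exon is a true positive only when both of its boundaries match a labelled
exon exactly; a gene is a true positive only when all its exons are correct
and no extra exons were predicted.  Undefined ratios (zero denominators)
are reported as NaN, never as 0.

The GC-variability statistics characterize genes with strong internal GC
heterogeneity: *GC-distance* is the largest difference of GC content
between any two exons of a gene, and the per-gene *SD* is the population
standard deviation of the exon GC profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .gc import gene_gc_profile
from .genes import GeneStructure

__all__ = [
    "LevelCounts",
    "EvalReport",
    "evaluate",
    "gc_distance",
    "gene_gc_sd",
    "compare_tools",
    "ToolComparison",
]


@dataclass
class LevelCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def sen(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def spe(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")


@dataclass
class EvalReport:
    base: LevelCounts
    exon: LevelCounts
    gene: LevelCounts
    matched_truth_ids: list[str] = field(default_factory=list)
    matched_pred_ids: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        out = {}
        for level in ("base", "exon", "gene"):
            c: LevelCounts = getattr(self, level)
            out[level] = {"tp": c.tp, "fp": c.fp, "fn": c.fn, "sen": c.sen, "spe": c.spe}
        return out


def _coding_positions(genes: list[GeneStructure]) -> set[tuple[str, str, int]]:
    out = set()
    for g in genes:
        for (s, e) in g.exons:
            for p in range(s, e):
                out.add((g.seqid, g.strand, p))
    return out


def _exon_set(genes: list[GeneStructure]) -> set[tuple[str, str, int, int]]:
    return {(g.seqid, g.strand, s, e) for g in genes for (s, e) in g.exons}


def _gene_key(g: GeneStructure) -> tuple:
    return (g.seqid, g.strand, tuple(g.exons))


def evaluate(
    pred: list[GeneStructure],
    truth: list[GeneStructure],
    seq_lengths: dict[str, int] | None = None,
) -> EvalReport:
    """Compare predictions against reference annotations on shared regions."""
    if seq_lengths:
        for g in list(pred) + list(truth):
            if g.seqid in seq_lengths and g.span[1] > seq_lengths[g.seqid]:
                raise ValueError(f"gene {g.gene_id} exceeds sequence {g.seqid}")
    pb, tb = _coding_positions(pred), _coding_positions(truth)
    base = LevelCounts(len(pb & tb), len(pb - tb), len(tb - pb))
    pe, te = _exon_set(pred), _exon_set(truth)
    exon = LevelCounts(len(pe & te), len(pe - te), len(te - pe))
    truth_by_key = {}
    for g in truth:
        truth_by_key.setdefault(_gene_key(g), []).append(g)
    matched_truth, matched_pred = [], []
    used: set[int] = set()
    gene_tp = 0
    for g in pred:
        cands = truth_by_key.get(_gene_key(g), [])
        hit = next((t for t in cands if id(t) not in used), None)
        if hit is not None:
            used.add(id(hit))
            gene_tp += 1
            matched_truth.append(hit.gene_id)
            matched_pred.append(g.gene_id)
    gene = LevelCounts(gene_tp, len(pred) - gene_tp, len(truth) - gene_tp)
    return EvalReport(base, exon, gene, matched_truth, matched_pred)


def gc_distance(gene: GeneStructure, genome: dict[str, str] | str) -> float:
    """max - min of the per-exon GC profile (largest pairwise difference)."""
    profile = gene_gc_profile(gene, genome)
    return max(profile) - min(profile)


def gene_gc_sd(gene: GeneStructure, genome: dict[str, str] | str) -> float:
    """Population standard deviation of the per-exon GC profile."""
    return float(np.std(gene_gc_profile(gene, genome)))


@dataclass
class ToolComparison:
    unique_to_a: list[GeneStructure]
    unique_to_b: list[GeneStructure]
    common: list[GeneStructure]
    mean_sd: dict[str, float]
    mean_gc_distance: dict[str, float]


def compare_tools(
    preds_a: list[GeneStructure],
    preds_b: list[GeneStructure],
    truth: list[GeneStructure],
    genome: dict[str, str],
) -> ToolComparison:
    """Partition the correctly predicted truth genes into unique-to-A,
    unique-to-B and common, with mean per-gene SD and GC-distance for each
    partition (NaN when a partition is empty)."""
    keys_a = {_gene_key(g) for g in preds_a}
    keys_b = {_gene_key(g) for g in preds_b}
    unique_a, unique_b, common = [], [], []
    for t in truth:
        k = _gene_key(t)
        in_a, in_b = k in keys_a, k in keys_b
        if in_a and in_b:
            common.append(t)
        elif in_a:
            unique_a.append(t)
        elif in_b:
            unique_b.append(t)

    def summarize(genes: list[GeneStructure], fn) -> float:
        if not genes:
            return float("nan")
        return float(np.mean([fn(g, genome) for g in genes]))

    return ToolComparison(
        unique_a,
        unique_b,
        common,
        {
            "unique_to_a": summarize(unique_a, gene_gc_sd),
            "unique_to_b": summarize(unique_b, gene_gc_sd),
            "common": summarize(common, gene_gc_sd),
        },
        {
            "unique_to_a": summarize(unique_a, gc_distance),
            "unique_to_b": summarize(unique_b, gc_distance),
            "common": summarize(common, gc_distance),
        },
    )
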