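"""Model training: tier labelling, transition counting and estimation,
emission/length fitting, cutoff diagnostics and cross-validation.

Two transition-estimation strategies are supported.  ``mle`` applies the
maximum-likelihood estimator a_kl = A'_kl / sum_q A'_kq with Laplace-style
pseudocounts A'_kl = A_kl + r_kl directly on the tiered state set.
``equal`` first estimates a tier-blind matrix on the collapsed state set and
then divides every edge entering a tier triple equally among the three tier
states — the strategy of starting from known single-tier transition
probabilities when tiered training data are scarce.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .emissions import (
    fit_coding_markov,
    fit_homogeneous_markov,
    fit_length_distribution,
    fit_site_window,
)
from .gc import classify_gc, gc_content
from .genes import GeneStructure, revcomp, validate_gene
from .model import (
    DONOR_CONSENSUS,
    GhmmModel,
    MIN_EXON_LEN,
    ModelConfig,
    TransitionMatrix,
    acceptor_consensus,
    uniform_model,
)
from .states import EXON_CATEGORIES, StateSet, TIERS, build_state_set, build_topology, collapse_map

__all__ = [
    "TrainingCorpus",
    "TransitionCounts",
    "LabelledCorpus",
    "label_training_exons",
    "count_transitions",
    "estimate_transitions_mle",
    "split_transitions_equally",
    "train_model",
    "cutoff_coverage_report",
    "kfold_cross_validate",
]

_SUFFIX = {"high": "_H", "medium": "_M", "low": "_L", None: ""}


@dataclass
class TrainingCorpus:
    """Named sequences plus per-sequence gene annotations."""

    sequences: dict[str, str]
    annotations: dict[str, list[GeneStructure]]

    def __post_init__(self) -> None:
        for seqid in self.annotations:
            if seqid not in self.sequences:
                raise ValueError(f"annotations reference unknown sequence {seqid!r}")

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.annotations.values())

    def region_ids(self) -> list[str]:
        return sorted(self.sequences)

    def subset(self, seqids: list[str]) -> "TrainingCorpus":
        return TrainingCorpus(
            {s: self.sequences[s] for s in seqids},
            {s: self.annotations.get(s, []) for s in seqids},
        )


@dataclass
class TransitionCounts:
    state_set: StateSet
    A: np.ndarray  # observed transition counts
    r: float  # pseudocount added on every support edge

    def count(self, a: str, b: str) -> float:
        return float(self.A[self.state_set.ordinal(a), self.state_set.ordinal(b)])


@dataclass
class _ExonRecord:
    category: str
    tier: str | None
    c0: int  # codon position of the first transcript base
    seq: str  # transcript orientation
    context: str  # transcript-preceding bases


@dataclass
class _GeneRecord:
    gene: GeneStructure
    path: list[str]  # implied state names, gene states only (no IR)
    exons: list[_ExonRecord]
    intron_interiors: list[tuple[str, str]]  # (sequence, context), transcript orientation
    short_interior_lengths: list[int]
    geo_tails: list[tuple[str, int]]  # (I_geo state name, tail length) for long introns
    donors: list[str]
    acceptors: list[str]


@dataclass
class LabelledCorpus:
    corpus: TrainingCorpus
    config: ModelConfig
    tiered: bool
    records: dict[str, list[_GeneRecord]]  # per sequence id
    skipped: list[tuple[str, str]]  # (gene id, reason)

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.records.values())


def _exon_phase_names(gene: GeneStructure, tiers: list[str | None]) -> list[tuple[str, str, int, int]]:
    """Per exon in transcript order: (state base name, category, exponent,
    entry codon position)."""
    tx = gene.exons_in_transcript_order()
    n = len(tx)
    out = []
    cum = 0
    for m, (s, e) in enumerate(tx, start=1):
        entry = cum % 3
        cum += e - s
        exit_ = cum % 3
        if n == 1:
            base, cat = ("E_single" if gene.strand == "forward" else "rE_single"), "exon_single"
        elif m == 1:
            if gene.strand == "forward":
                base, cat = f"E_init_{exit_}", "exon_initial"
            else:
                base, cat = "rE_init", "exon_initial"
        elif m == n:
            if gene.strand == "forward":
                base, cat = "E_term", "exon_terminal"
            else:
                base, cat = f"rE_term_{entry}", "exon_terminal"
        else:
            if gene.strand == "forward":
                base, cat = f"E_int_{exit_}", "exon_internal"
            else:
                base, cat = f"rE_int_{entry}", "exon_internal"
        out.append((base, cat, exit_ if gene.strand == "forward" else entry, entry))
    return out


def _gene_record(
    gene: GeneStructure, seq: str, cfg: ModelConfig, tiered: bool
) -> _GeneRecord:
    """Label one structurally valid gene and derive its implied state path."""
    Wd, Wa, d, k = cfg.dss_window, cfg.ass_window, cfg.d, cfg.k
    tiers = list(TIERS) if tiered else [None]
    tx = gene.exons_in_transcript_order()
    names = _exon_phase_names(gene, tiers)

    exon_recs: list[_ExonRecord] = []
    labels_tx: list[tuple[str, int | None, str | None]] = []
    path: list[str] = []
    interiors: list[tuple[str, str]] = []
    short_lens: list[int] = []
    geo_tails: list[tuple[str, int]] = []
    donors: list[str] = []
    acceptors: list[str] = []

    for m, ((s, e), (base, cat, expo, entry)) in enumerate(zip(tx, names), start=1):
        exon_seq = seq[s:e] if gene.strand == "forward" else revcomp(seq[s:e])
        if tiered:
            tier = classify_gc(gc_content(exon_seq), cfg.low_t, cfg.high_t)
        else:
            tier = None
        state_name = base + _SUFFIX[tier]
        phased = base.startswith(("E_init_", "E_int_", "rE_term_", "rE_int_"))
        labels_tx.append((cat, expo if phased else None, tier))
        if gene.strand == "forward":
            ctx = seq[max(0, s - k) : s]
        else:
            ctx = revcomp(seq[e : e + k])
        exon_recs.append(_ExonRecord(cat, tier, entry, exon_seq, ctx))

        if m < len(tx):  # intron after this exon (transcript order)
            nxt = tx[m]
            if gene.strand == "forward":
                ia, ib = e, nxt[0]
                donor = seq[ia : ia + Wd]
                acceptor = seq[ib - Wa : ib]
                interior = seq[ia + Wd : ib - Wa]
                ictx = seq[max(0, ia + Wd - k) : ia + Wd]
            else:
                ia, ib = nxt[1], s
                donor = revcomp(seq[ib - Wd : ib])
                acceptor = revcomp(seq[ia : ia + Wa])
                interior = revcomp(seq[ia + Wa : ib - Wd])
                ictx = revcomp(seq[ib : ib + k])
            donors.append(donor)
            acceptors.append(acceptor)
            interiors.append((interior, ictx))
            ilen = len(interior)
            x = (sum(b - a for a, b in tx[:m])) % 3  # phase carried across this intron
            if gene.strand == "forward":
                intron_states = (
                    [f"DSS_{x}", f"I_short_{x}", f"ASS_{x}"]
                    if ilen <= d
                    else [f"DSS_{x}", f"I_fixed_{x}", f"I_geo_{x}", f"ASS_{x}"]
                )
            else:
                intron_states = (
                    [f"rASS_{x}", f"rI_short_{x}", f"rDSS_{x}"]
                    if ilen <= d
                    else [f"rASS_{x}", f"rI_fixed_{x}", f"rI_geo_{x}", f"rDSS_{x}"]
                )
            if ilen <= d:
                short_lens.append(ilen)
            else:
                geo_state = f"I_geo_{x}" if gene.strand == "forward" else f"rI_geo_{x}"
                geo_tails.append((geo_state, ilen - d))
            path.append(state_name)
            path.extend(intron_states)
        else:
            path.append(state_name)

    if gene.strand == "reverse":
        # the walk above is in transcript order; genomic decoding order is its
        # reverse.  The reverse-intron state groups were already named in
        # genomic order (rASS before rDSS), so reverse the group sequence
        # while keeping each group's internal order.
        groups: list[list[str]] = []
        i = 0
        for m in range(len(tx)):
            groups.append([path[i]])
            i += 1
            if m < len(tx) - 1:
                glen = 3 if path[i + 1].startswith("rI_short") else 4
                groups.append(path[i : i + glen])
                i += glen
        groups.reverse()
        path = [s for g in groups for s in g]

    # labels in genomic order for the GeneStructure
    labels_geo = labels_tx if gene.strand == "forward" else list(reversed(labels_tx))
    gene.exon_labels = labels_geo
    return _GeneRecord(
        gene, path, exon_recs, interiors, short_lens, geo_tails, donors, acceptors
    )


def label_training_exons(
    corpus: TrainingCorpus, config: ModelConfig, tiered: bool = True
) -> LabelledCorpus:
    """Validate genes, classify their exons into GC tiers and assign each to
    its HMM exon state.  Invalid genes are skipped with a logged reason."""
    records: dict[str, list[_GeneRecord]] = {}
    skipped: list[tuple[str, str]] = []
    for seqid in corpus.region_ids():
        seq = corpus.sequences[seqid]
        recs = []
        prev_end = 0
        for gene in sorted(corpus.annotations.get(seqid, []), key=lambda g: g.span):
            problems = validate_gene(gene, seq, min_intron=config.min_intron_len)
            s0, e0 = gene.span
            if s0 < 1 or e0 > len(seq) - 1:
                problems.append("gene touches the region boundary")
            if s0 <= prev_end and prev_end > 0:
                problems.append("gene overlaps or abuts the previous gene")
            for (s, e) in gene.exons:
                if e - s > config.max_exon_len:
                    problems.append(f"exon longer than the duration cap {config.max_exon_len}")
            if problems:
                skipped.append((gene.gene_id, "; ".join(problems)))
                warnings.warn(f"skipping gene {gene.gene_id}: {problems[0]}")
                continue
            prev_end = e0
            recs.append(_gene_record(gene, seq, config, tiered))
        records[seqid] = recs
    return LabelledCorpus(corpus, config, tiered, records, skipped)


def count_transitions(labelled: LabelledCorpus, state_set: StateSet) -> TransitionCounts:
    """Tally adjacent state pairs along each region's implied state path."""
    n = len(state_set)
    A = np.zeros((n, n))
    ir = state_set.ordinal("IR")
    for seqid, recs in labelled.records.items():
        L = len(labelled.corpus.sequences[seqid])
        gene_bases = sum(r.gene.coding_length() + _intron_span(r) for r in recs)
        spans = sum(r.gene.span[1] - r.gene.span[0] for r in recs)
        ir_bases = L - spans
        n_runs = len(recs) + 1  # gaps before/between/after genes (all nonempty: validated)
        A[ir, ir] += max(ir_bases - n_runs, 0)
        for rec in recs:
            prev = ir
            for name in rec.path:
                cur = state_set.ordinal(name)
                A[prev, cur] += 1
                prev = cur
            A[prev, ir] += 1
            for geo_state, g in rec.geo_tails:
                # a geometric tail of g bases makes g-1 self loops
                o = state_set.ordinal(geo_state)
                A[o, o] += g - 1
    return TransitionCounts(state_set, A, labelled.config.pseudocount)


def _intron_span(rec: _GeneRecord) -> int:
    s, e = rec.gene.span
    return (e - s) - rec.gene.coding_length()


def estimate_transitions_mle(
    counts: TransitionCounts, pseudocount: float | None = None
) -> TransitionMatrix:
    """Row-normalized counts with pseudocounts on every support edge.

    A state whose row is still all zero after pseudocounts (r = 0 and no
    observations) falls back to a uniform distribution over its legal edges.
    """
    r = counts.r if pseudocount is None else pseudocount
    ss = counts.state_set
    support = build_topology(ss)
    n = len(ss)
    probs = np.zeros((n, n))
    out_edges: dict[int, list[int]] = {}
    for (a, b) in support:
        out_edges.setdefault(ss.ordinal(a), []).append(ss.ordinal(b))
    for ia, outs in out_edges.items():
        row = np.array([counts.A[ia, ib] + r for ib in outs])
        tot = row.sum()
        if tot <= 0:
            row = np.full(len(outs), 1.0 / len(outs))
        else:
            row = row / tot
        for ib, p in zip(outs, row):
            probs[ia, ib] = p
    return TransitionMatrix(ss, probs)


def split_transitions_equally(base: TransitionMatrix) -> TransitionMatrix:
    """Expand a collapsed (single-tier) matrix onto the tiered state set:
    every edge into a tier triple carries one third of the base probability;
    edges out of a triple replicate the base row; other edges are copied."""
    if base.state_set.tiered:
        raise ValueError("base matrix must live on the collapsed state set")
    tiered = build_state_set(tiered=True)
    cmap = collapse_map(tiered)
    support = build_topology(tiered)
    n = len(tiered)
    probs = np.zeros((n, n))
    for (u, v) in support:
        p = base.p(cmap[u], cmap[v])
        sv = tiered[v]
        if sv.is_exon:
            p /= 3.0
        probs[tiered.ordinal(u), tiered.ordinal(v)] = p
    return TransitionMatrix(tiered, probs)


def cutoff_coverage_report(counts: TransitionCounts, threshold: int = 5) -> list[tuple[str, str, int]]:
    """Support edges observed fewer than ``threshold`` times — guidance for
    choosing cutoffs under which training covers all transitions."""
    ss = counts.state_set
    out = []
    for (a, b) in sorted(build_topology(ss)):
        c = counts.A[ss.ordinal(a), ss.ordinal(b)]
        if c < threshold:
            out.append((a, b, int(c)))
    return out


def _fit_emissions(labelled: LabelledCorpus, cfg: ModelConfig, tiered: bool):
    tiers = list(TIERS) if tiered else [None]
    coding_data: dict[tuple[str, str | None], list] = {
        (c, t): [] for c in EXON_CATEGORIES for t in tiers
    }
    length_data: dict[tuple[str, str | None], list[int]] = {
        (c, t): [] for c in EXON_CATEGORIES for t in tiers
    }
    intron_seqs: list = []
    donors: list[str] = []
    acceptors: list[str] = []
    short_lens: list[int] = []
    ir_seqs: list = []

    for seqid, recs in labelled.records.items():
        seq = labelled.corpus.sequences[seqid]
        # intergenic stretches
        pos = 0
        for rec in sorted(recs, key=lambda r: r.gene.span):
            s, e = rec.gene.span
            if s > pos:
                ir_seqs.append(seq[pos:s])
            pos = e
        if pos < len(seq):
            ir_seqs.append(seq[pos:])
        for rec in recs:
            for ex in rec.exons:
                coding_data[(ex.category, ex.tier)].append((ex.seq, ex.c0, ex.context))
                length_data[(ex.category, ex.tier)].append(len(ex.seq))
            intron_seqs.extend((s, 0, c) for s, c in rec.intron_interiors if s)
            donors.extend(rec.donors)
            acceptors.extend(rec.acceptors)
            short_lens.extend(rec.short_interior_lengths)

    coding = {}
    lengths = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # one coding chain per GC tier, shared across exon categories: the
        # tier states are the model's resolution axis, while start/stop
        # syntax is enforced by hard constraints rather than composition
        per_tier = {}
        for t in tiers:
            pooled = [item for c in EXON_CATEGORIES for item in coding_data[(c, t)]]
            per_tier[t] = fit_coding_markov(pooled, cfg.k)
        for key in coding_data:
            coding[key] = per_tier[key[1]]
        for key, ls in length_data.items():
            if ls:
                lengths[key] = fit_length_distribution(ls, cfg.max_exon_len, cfg.length_bandwidth)
            else:
                lengths[key] = uniform_model(cfg, tiered).length_distribution(*key)
        intron_model = fit_homogeneous_markov(intron_seqs, cfg.k_noncoding)
        ir_model = fit_homogeneous_markov(ir_seqs, cfg.k_noncoding)
        donor_model = fit_site_window(donors, cfg.dss_window, DONOR_CONSENSUS)
        acceptor_model = fit_site_window(acceptors, cfg.ass_window, acceptor_consensus(cfg.ass_window))
        if short_lens:
            intron_length = fit_length_distribution(short_lens, cfg.d, min(cfg.length_bandwidth, 3))
        else:
            intron_length = uniform_model(cfg, tiered).intron_length
    return coding, lengths, ir_model, intron_model, donor_model, acceptor_model, intron_length


def train_model(
    corpus: TrainingCorpus,
    config: ModelConfig,
    strategy: str = "mle",
    tiered: bool = True,
) -> GhmmModel:
    """Full training pass: tier labelling, transition estimation by the
    chosen strategy, emission and length fitting."""
    if strategy not in ("mle", "equal"):
        raise ValueError("strategy must be 'mle' or 'equal'")
    labelled = label_training_exons(corpus, config, tiered)
    if labelled.n_genes == 0:
        raise ValueError("no structurally valid genes in the training corpus")
    state_set = build_state_set(tiered=tiered)
    if strategy == "mle" or not tiered:
        counts = count_transitions(labelled, state_set)
        transitions = estimate_transitions_mle(counts)
    else:
        collapsed_labelled = label_training_exons(corpus, config, tiered=False)
        base_counts = count_transitions(collapsed_labelled, build_state_set(tiered=False))
        transitions = split_transitions_equally(estimate_transitions_mle(base_counts))
    coding, lengths, ir_m, intron_m, donor_m, acc_m, ilen = _fit_emissions(labelled, config, tiered)
    return GhmmModel(
        state_set, transitions, coding, lengths, ir_m, intron_m, donor_m, acc_m, ilen, config
    )


@dataclass
class CvResult:
    best_low_t: float
    best_high_t: float
    per_cutoff: dict  # (lowT, highT) -> {"folds": [EvalReport...], "mean_sen": .., "mean_spe": ..}


def kfold_cross_validate(
    corpus: TrainingCorpus,
    config: ModelConfig,
    folds: int = 10,
    seed: int = 0,
    grid: list[tuple[float, float]] | None = None,
    strategy: str = "mle",
    tiered: bool = True,
) -> CvResult:
    """Shuffle regions with the given seed, split into near-equal folds,
    hold each out once, and grid-search (lowT, highT) by average exon-level
    performance; ties go to the smallest cutoff pair."""
    from .decoder import path_to_genes, viterbi_decode
    from .evaluation import evaluate

    regions = corpus.region_ids()
    if len(regions) < folds:
        raise ValueError(f"{len(regions)} regions is fewer than {folds} folds")
    rng = np.random.default_rng(seed)
    order = [regions[i] for i in rng.permutation(len(regions))]
    parts = [order[i::folds] for i in range(folds)]
    grid = grid or [(config.low_t, config.high_t)]

    per_cutoff = {}
    best_key, best_score = None, -np.inf
    for (lo, hi) in sorted(grid):
        cfg = ModelConfig(**{**config.__dict__, "low_t": lo, "high_t": hi})
        reports = []
        senspe = []
        for f in range(folds):
            test_ids = parts[f]
            train_ids = [r for r in order if r not in set(test_ids)]
            model = train_model(corpus.subset(train_ids), cfg, strategy=strategy, tiered=tiered)
            preds, truths = [], []
            for sid in test_ids:
                seq = corpus.sequences[sid]
                parse = viterbi_decode(seq, model)
                preds.extend(path_to_genes(parse, seqid=sid))
                truths.extend(corpus.annotations.get(sid, []))
            rep = evaluate(preds, truths)
            reports.append(rep)
            sen = 0.0 if np.isnan(rep.exon.sen) else rep.exon.sen
            spe = 0.0 if np.isnan(rep.exon.spe) else rep.exon.spe
            senspe.append((sen + spe) / 2.0)
        score = float(np.mean(senspe))
        per_cutoff[(lo, hi)] = {
            "folds": reports,
            "mean_exon_sen": float(np.mean([r.exon.sen for r in reports])),
            "mean_exon_spe": float(np.mean([r.exon.spe for r in reports])),
            "score": score,
        }
        if score > best_score:  # strict: earlier (smaller) pair wins ties
            best_key, best_score = (lo, hi), score
    return CvResult(best_key[0], best_key[1], per_cutoff)
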