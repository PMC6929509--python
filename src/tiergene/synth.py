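"""Synthetic genomes with annotated multi-exon genes and controlled exon GC.

The generator emulates the salient feature of grass genomes: per-gene exon
GC profiles that either fall steeply 5'-to-3' (negative gradient) or sit
flat at a high, medium or low level.  Genes have ATG starts, GT..AG
introns, a closing stop codon and no in-frame stop codons (including stops
split across introns); exon base composition is drawn with exact G+C counts
so every exon lands within a small tolerance of its GC target.  Within an
exon the G+C mass is skewed toward the third codon position, mirroring the
GC3-driven gradients of real grass genes and giving the coding chains a
learnable periodic signal.

Two entry points: :func:`generate_corpus` draws gene architectures from the
configured ranges; :func:`generate_from_model` samples gene structures from
a known model's transition matrix and length distributions (used for
parameter-recovery experiments), with exon GC targets placed mid-tier so
that tier labelling recovers the sampled states deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genes import GeneStructure, STOP_CODONS, revcomp
from .model import GhmmModel, ModelConfig
from .training import TrainingCorpus

__all__ = ["SynthConfig", "generate_corpus", "generate_from_model", "corpus_stats"]

MODES = ("negative_gradient", "flat_high", "flat_medium", "flat_low")


@dataclass
class SynthConfig:
    """Study conditions for the synthetic corpus."""

    seed: int
    n_regions: int = 60
    region_length: int = 5000
    genes_per_region: tuple[int, int] = (1, 2)
    exon_count_range: tuple[int, int] = (3, 5)
    exon_len_range: tuple[int, int] = (60, 210)
    intron_len_range: tuple[int, int] = (50, 120)
    mode_weights: dict = field(
        default_factory=lambda: {
            "negative_gradient": 0.5,
            "flat_high": 1.0 / 6.0,
            "flat_medium": 1.0 / 6.0,
            "flat_low": 1.0 / 6.0,
        }
    )
    gradient_start: float = 0.70
    gradient_end: float = 0.35
    flat_targets: dict = field(
        default_factory=lambda: {"flat_high": 0.68, "flat_medium": 0.50, "flat_low": 0.37}
    )
    strand_p: float = 0.5
    intergenic_gc: float = 0.35
    intron_gc: float = 0.35
    single_exon_prob: float = 0.04  # flat modes only; gradients need several exons
    codon_gc3_skew: float = 0.15
    min_gap: int = 150

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for v in list(self.mode_weights.values()) + [self.strand_p, self.single_exon_prob]:
            if not 0 <= v <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for g in [self.gradient_start, self.gradient_end, self.intergenic_gc, self.intron_gc] + list(
            self.flat_targets.values()
        ):
            if not 0 < g < 1:
                raise ValueError("GC targets must lie in (0, 1)")


_BASES = np.array(list("ACGT"))


def _random_gc_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    if length <= 0:
        return ""
    n_gc = int(round(gc * length))
    arr = np.empty(length, dtype="<U1")
    gc_pos = rng.choice(length, size=n_gc, replace=False)
    mask = np.zeros(length, dtype=bool)
    mask[gc_pos] = True
    arr[mask] = rng.choice(["G", "C"], size=n_gc)
    arr[~mask] = rng.choice(["A", "T"], size=length - n_gc)
    return "".join(arr)


def _exon_sequence(
    rng: np.random.Generator,
    length: int,
    c0: int,
    gc: float,
    skew: float,
    start_atg: bool,
    end_stop: bool,
) -> list[str]:
    """Transcript-orientation exon with exact G+C count, GC3-skewed."""
    chars = [""] * length
    fixed = np.zeros(length, dtype=bool)
    if start_atg:
        if length < 3 or c0 != 0:
            raise ValueError("ATG start requires codon position 0 and length >= 3")
        chars[0:3] = ["A", "T", "G"]
        fixed[0:3] = True
    if end_stop:
        stop = STOP_CODONS[rng.integers(0, len(STOP_CODONS))]
        if length < (6 if start_atg else 3):
            raise ValueError("exon too short for its stop codon")
        chars[length - 3 :] = list(stop)
        fixed[length - 3 :] = True
    fixed_gc = sum(1 for i in range(length) if fixed[i] and chars[i] in "GC")
    total_gc = int(round(gc * length))
    budget = total_gc - fixed_gc
    cps = (np.arange(length) + c0) % 3
    free_idx = [np.where(~fixed & (cps == c))[0] for c in range(3)]
    n_free = np.array([len(ix) for ix in free_idx])
    budget = min(max(budget, 0), int(n_free.sum()))
    class_gc_target = np.clip([gc, gc - skew, gc + skew], 0.02, 0.98) * n_free
    if class_gc_target.sum() <= 0:
        alloc = np.zeros(3, dtype=int)
    else:
        alloc = np.floor(class_gc_target * budget / class_gc_target.sum()).astype(int)
    alloc = np.minimum(alloc, n_free)
    # distribute the remainder to classes with headroom, GC3 first
    for c in (2, 0, 1):
        while alloc.sum() < budget and alloc[c] < n_free[c]:
            alloc[c] += 1
    for c in range(3):
        ix = free_idx[c]
        if len(ix) == 0:
            continue
        gc_sel = rng.choice(len(ix), size=alloc[c], replace=False) if alloc[c] else []
        is_gc = np.zeros(len(ix), dtype=bool)
        is_gc[list(gc_sel)] = True
        for flag, pos in zip(is_gc, ix):
            chars[pos] = ("G" if rng.random() < 0.5 else "C") if flag else ("A" if rng.random() < 0.5 else "T")
    return chars


def _fix_inframe_stops(
    rng: np.random.Generator,
    exon_chars: list[list[str]],
    exon_c0: list[int],
    fixed_masks: list[np.ndarray],
    max_iter: int = 500,
) -> bool:
    """Remove in-frame stop codons from the spliced CDS (the final codon is
    left alone) by swapping codon-position-0 bases within an exon; swaps
    stay within one codon-position class so composition is preserved."""
    for _ in range(max_iter):
        cds = "".join("".join(ch) for ch in exon_chars)
        bad = None
        for p in range(0, len(cds) - 3, 3):
            if cds[p : p + 3] in STOP_CODONS:
                bad = p
                break
        if bad is None:
            return True
        # locate the exon holding CDS position `bad`
        off = bad
        for ei, ch in enumerate(exon_chars):
            if off < len(ch):
                break
            off -= len(ch)
        chars, fixed, c0 = exon_chars[ei], fixed_masks[ei], exon_c0[ei]
        cls = (c0 + off) % 3  # == 0: the codon-start T
        cands = [
            q
            for q in range(len(chars))
            if (c0 + q) % 3 == cls and not fixed[q] and chars[q] != "T" and q != off
        ]
        if not cands or fixed[off]:
            return False
        q = cands[rng.integers(0, len(cands))]
        chars[off], chars[q] = chars[q], chars[off]
    return False


def _assemble_gene(
    rng: np.random.Generator,
    exon_lengths: list[int],
    exon_gcs: list[float],
    intron_lengths: list[int],
    strand: str,
    skew: float,
    intron_gc: float,
) -> tuple[str, list[tuple[int, int]]] | None:
    """Build one gene (transcript design, genomic orientation output).

    Returns (gene sequence, exon intervals relative to the gene start in
    genomic coordinates) or None when constraint fixing failed.
    """
    n = len(exon_lengths)
    total = sum(exon_lengths)
    if total % 3 != 0:
        raise ValueError("total coding length must be divisible by 3")
    exon_chars: list[list[str]] = []
    fixed_masks: list[np.ndarray] = []
    exon_c0: list[int] = []
    cum = 0
    for m, (ln, g) in enumerate(zip(exon_lengths, exon_gcs)):
        c0 = cum % 3
        chars = _exon_sequence(
            rng,
            ln,
            c0,
            g,
            skew,
            start_atg=(m == 0),
            end_stop=(m == n - 1),
        )
        fixed = np.zeros(ln, dtype=bool)
        if m == 0:
            fixed[0:3] = True
        if m == n - 1:
            fixed[ln - 3 :] = True
        exon_chars.append(chars)
        fixed_masks.append(fixed)
        exon_c0.append(c0)
        cum += ln
    if not _fix_inframe_stops(rng, exon_chars, exon_c0, fixed_masks):
        return None
    introns = [
        "GT" + _random_gc_seq(rng, il - 4, intron_gc) + "AG" for il in intron_lengths
    ]
    parts = []
    exon_spans_tx = []
    pos = 0
    for m in range(n):
        seq = "".join(exon_chars[m])
        exon_spans_tx.append((pos, pos + len(seq)))
        parts.append(seq)
        pos += len(seq)
        if m < n - 1:
            parts.append(introns[m])
            pos += len(introns[m])
    gene_tx = "".join(parts)
    if strand == "forward":
        return gene_tx, exon_spans_tx
    glen = len(gene_tx)
    spans = sorted((glen - e, glen - s) for (s, e) in exon_spans_tx)
    return revcomp(gene_tx), spans


def _place_genes(
    rng: np.random.Generator,
    region_len: int,
    gene_seqs: list[str],
    gene_exons: list[list[tuple[int, int]]],
    strands: list[str],
    seqid: str,
    intergenic_gc: float,
    min_gap: int,
) -> tuple[str, list[GeneStructure]] | None:
    total_genes = sum(len(s) for s in gene_seqs)
    n_gaps = len(gene_seqs) + 1
    spare = region_len - total_genes - n_gaps * min_gap
    if spare < 0:
        return None
    cuts = np.sort(rng.integers(0, spare + 1, size=n_gaps - 1)) if n_gaps > 1 else np.array([], dtype=int)
    gap_sizes = np.diff(np.concatenate([[0], cuts, [spare]])) + min_gap
    parts = []
    genes = []
    pos = 0
    for i, gseq in enumerate(gene_seqs):
        gap = int(gap_sizes[i])
        parts.append(_random_gc_seq(rng, gap, intergenic_gc))
        pos += gap
        exons = [(pos + s, pos + e) for (s, e) in gene_exons[i]]
        genes.append(GeneStructure(f"{seqid}.g{i + 1}", seqid, strands[i], exons))
        parts.append(gseq)
        pos += len(gseq)
    parts.append(_random_gc_seq(rng, int(gap_sizes[-1]), intergenic_gc))
    return "".join(parts), genes


def _gene_design(rng: np.random.Generator, cfg: SynthConfig) -> tuple[list[int], list[float], list[int], str, str]:
    modes = list(cfg.mode_weights)
    w = np.array([cfg.mode_weights[m] for m in modes], dtype=float)
    mode = modes[rng.choice(len(modes), p=w / w.sum())]
    if mode == "negative_gradient":
        n_exons = int(rng.integers(max(2, cfg.exon_count_range[0]), cfg.exon_count_range[1] + 1))
    elif rng.random() < cfg.single_exon_prob:
        n_exons = 1
    else:
        n_exons = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
    lo, hi = cfg.exon_len_range
    lengths = [int(rng.integers(lo, hi + 1)) for _ in range(n_exons)]
    excess = sum(lengths) % 3
    lengths[-1] -= excess
    if mode == "negative_gradient":
        gcs = list(np.linspace(cfg.gradient_start, cfg.gradient_end, n_exons))
    else:
        gcs = [cfg.flat_targets[mode]] * n_exons
    ilo, ihi = cfg.intron_len_range
    introns = [int(rng.integers(ilo, ihi + 1)) for _ in range(n_exons - 1)]
    strand = "forward" if rng.random() >= cfg.strand_p else "reverse"
    return lengths, gcs, introns, strand, mode


def generate_corpus(config: SynthConfig) -> TrainingCorpus:
    """Regions of low-GC intergenic background with embedded genes whose
    exon GC follows the configured modes.  Fully reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    sequences: dict[str, str] = {}
    annotations: dict[str, list[GeneStructure]] = {}
    for r in range(config.n_regions):
        seqid = f"region{r:04d}"
        for _attempt in range(20):
            n_genes = int(rng.integers(config.genes_per_region[0], config.genes_per_region[1] + 1))
            gene_seqs, gene_exons, strands = [], [], []
            ok = True
            for _g in range(n_genes):
                lengths, gcs, introns, strand, _mode = _gene_design(rng, config)
                built = _assemble_gene(
                    rng, lengths, gcs, introns, strand, config.codon_gc3_skew, config.intron_gc
                )
                if built is None:
                    ok = False
                    break
                gene_seqs.append(built[0])
                gene_exons.append(built[1])
                strands.append(strand)
            if not ok:
                continue
            placed = _place_genes(
                rng,
                config.region_length,
                gene_seqs,
                gene_exons,
                strands,
                seqid,
                config.intergenic_gc,
                config.min_gap,
            )
            if placed is None:
                continue
            sequences[seqid], annotations[seqid] = placed
            break
        else:
            raise RuntimeError(f"could not place genes in region {seqid}; config infeasible")
    return TrainingCorpus(sequences, annotations)


# -- sampling gene structures from a known model --------------------------------


def _sample_length(rng, ldist, residue: int | None, min_len: int) -> int:
    pmf = ldist.pmf().copy()
    lens = np.arange(1, len(pmf) + 1)
    mask = lens >= min_len
    if residue is not None:
        mask &= (lens % 3) == residue
    pmf = np.where(mask, pmf, 0.0)
    if pmf.sum() <= 0:
        cand = lens[mask]
        if len(cand) == 0:
            raise ValueError("no legal length for this state")
        return int(cand[rng.integers(0, len(cand))])
    return int(rng.choice(lens, p=pmf / pmf.sum()))


def _row_choice(rng, model: GhmmModel, from_state: str, exclude: tuple[str, ...] = ()) -> str:
    ss = model.state_set
    row = model.transitions.probs[ss.ordinal(from_state)].copy()
    for name in exclude:
        row[ss.ordinal(name)] = 0.0
    tot = row.sum()
    if tot <= 0:
        raise ValueError(f"state {from_state} has no sampleable exits")
    return ss[int(rng.choice(len(row), p=row / tot))].name


def _tier_targets(cfg: ModelConfig) -> dict[str, float]:
    return {
        "low": max(0.08, cfg.low_t - 0.10),
        "medium": (cfg.low_t + cfg.high_t) / 2.0,
        "high": min(0.92, cfg.high_t + 0.10),
    }


def generate_from_model(
    model: GhmmModel,
    n_genes: int,
    seed: int,
    genes_per_region: int = 8,
    tier_targets: dict[str, float] | None = None,
    skew: float = 0.12,
    intron_gc: float = 0.35,
) -> TrainingCorpus:
    """Sample gene structures from the model's transition matrix and length
    distributions and realize them as sequences.

    Exon GC targets sit well inside each tier band, short-intron interiors
    are drawn from the model's explicit distribution and long interiors as
    the fixed prefix plus a geometric tail, and intergenic gaps follow the
    intergenic self-loop, so retraining on the output recovers the matrix up
    to sampling noise.
    """
    from .decoder import _state_fields  # name parsing shared with the decoder

    cfg = model.config
    ss = model.state_set
    rng = np.random.default_rng(seed)
    targets = dict(tier_targets or _tier_targets(cfg))
    targets[None] = 0.5  # collapsed models: a single mid-band target
    p_ir = model.transitions.p("IR", "IR")
    q_geo = model.transitions.p("I_geo_0", "I_geo_0")

    def intron_total(from_splice_row: str) -> int:
        kind = _row_choice(rng, model, from_splice_row)
        if "short" in kind:
            interior = _sample_length(rng, model.intron_length, None, 1)
        else:
            interior = cfg.d + int(rng.geometric(max(1.0 - q_geo, 1e-6)))
        return cfg.dss_window + interior + cfg.ass_window

    def sample_gene() -> tuple[list[int], list[float], list[int], str]:
        entry = _row_choice(rng, model, "IR", exclude=("IR",))
        cat, phase, tier, strand = _state_fields(entry)
        lengths, gcs, introns = [], [], []
        if cat == "exon_single":
            ln = _sample_length(rng, model.length_distribution(cat, tier), 0, model.min_exon_len(cat))
            return [ln], [targets[tier]], [], strand
        if strand == "forward":
            # E_init_x: exit phase x = length mod 3
            x = phase
            ln = _sample_length(rng, model.length_distribution(cat, tier), x, model.min_exon_len(cat))
            lengths.append(ln)
            gcs.append(targets[tier])
            while True:
                introns.append(intron_total(f"DSS_{x}"))
                nxt = _row_choice(rng, model, f"ASS_{x}")
                ncat, nphase, ntier, _ = _state_fields(nxt)
                ldist = model.length_distribution(ncat, ntier)
                if ncat == "exon_terminal":
                    ln = _sample_length(rng, ldist, (-x) % 3, model.min_exon_len(ncat))
                    lengths.append(ln)
                    gcs.append(targets[ntier])
                    return lengths, gcs, introns, strand
                ln = _sample_length(rng, ldist, (nphase - x) % 3, model.min_exon_len(ncat))
                lengths.append(ln)
                gcs.append(targets[ntier])
                x = nphase
        # reverse strand, genomic walk: rE_term_x first (transcript-last exon)
        x = phase
        ln = _sample_length(
            rng, model.length_distribution(cat, tier), (-x) % 3, model.min_exon_len(cat)
        )
        rev_lengths = [ln]
        rev_gcs = [targets[tier]]
        rev_introns = []
        while True:
            rev_introns.append(intron_total(f"rASS_{x}"))
            nxt = _row_choice(rng, model, f"rDSS_{x}")
            ncat, nphase, ntier, _ = _state_fields(nxt)
            ldist = model.length_distribution(ncat, ntier)
            if ncat == "exon_initial":
                ln = _sample_length(rng, ldist, x % 3, model.min_exon_len(ncat))
                rev_lengths.append(ln)
                rev_gcs.append(targets[ntier])
                # genomic order walked right-to-left in transcript terms
                return list(reversed(rev_lengths)), list(reversed(rev_gcs)), list(reversed(rev_introns)), strand
            ln = _sample_length(rng, ldist, (x - nphase) % 3, model.min_exon_len(ncat))
            rev_lengths.append(ln)
            rev_gcs.append(targets[ntier])
            x = nphase

    sequences: dict[str, str] = {}
    annotations: dict[str, list[GeneStructure]] = {}
    made = 0
    region = 0
    while made < n_genes:
        seqid = f"sim{region:05d}"
        take = min(genes_per_region, n_genes - made)
        gene_seqs, gene_exons, strands = [], [], []
        while len(gene_seqs) < take:
            lengths, gcs, introns, strand = sample_gene()
            built = _assemble_gene(rng, lengths, gcs, introns, strand, skew, intron_gc)
            if built is None:
                continue
            gene_seqs.append(built[0])
            gene_exons.append(built[1])
            strands.append(strand)
        parts, genes = [], []
        pos = 0
        for i, gseq in enumerate(gene_seqs):
            gap = int(rng.geometric(max(1.0 - p_ir, 1e-6)))
            parts.append(_random_gc_seq(rng, gap, intron_gc))
            pos += gap
            exons = [(pos + s, pos + e) for (s, e) in gene_exons[i]]
            genes.append(GeneStructure(f"{seqid}.g{i + 1}", seqid, strands[i], exons))
            parts.append(gseq)
            pos += len(gseq)
        parts.append(_random_gc_seq(rng, int(rng.geometric(max(1.0 - p_ir, 1e-6))), intron_gc))
        sequences[seqid] = "".join(parts)
        annotations[seqid] = genes
        made += take
        region += 1
    return TrainingCorpus(sequences, annotations)


def corpus_stats(corpus: TrainingCorpus) -> dict:
    """Summary statistics sufficient to verify a corpus against its config."""
    from .evaluation import gc_distance, gene_gc_sd
    from .gc import gene_gc_profile

    exon_gc: list[float] = []
    exon_lens: list[int] = []
    intron_lens: list[int] = []
    gdist: list[float] = []
    gsd: list[float] = []
    n_genes = 0
    for seqid, genes in corpus.annotations.items():
        seq = corpus.sequences[seqid]
        for g in genes:
            n_genes += 1
            exon_gc.extend(gene_gc_profile(g, seq))
            exon_lens.extend(e - s for (s, e) in g.exons)
            tx = g.exons
            intron_lens.extend(b[0] - a[1] for a, b in zip(tx, tx[1:]))
            gdist.append(gc_distance(g, seq))
            gsd.append(gene_gc_sd(g, seq))
    hist, edges = np.histogram(exon_gc, bins=20, range=(0.0, 1.0))
    return {
        "n_genes": n_genes,
        "n_exons": len(exon_gc),
        "exon_gc": exon_gc,
        "exon_gc_hist": (hist.tolist(), edges.tolist()),
        "exon_lengths": exon_lens,
        "intron_lengths": intron_lens,
        "gene_gc_distance": gdist,
        "gene_gc_sd": gsd,
        "mean_gc_distance": float(np.mean(gdist)) if gdist else float("nan"),
        "mean_gc_sd": float(np.mean(gsd)) if gsd else float("nan"),
    }
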