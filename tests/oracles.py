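"""Independent oracles used by the test suite and the acceptance script.

The parse enumerator walks every legal segmentation of a sequence (merged
form: intergenic and geometric-intron runs are single segments) and scores
each candidate with the explicit path re-scorer, entirely independently of
the Viterbi dynamic program.  Only practical for short sequences with small
duration caps.
"""

from __future__ import annotations

import numpy as np

from tiergene.decoder import Parse, Segment, score_fixed_path
from tiergene.emissions import LOG_QUARTER
from tiergene.model import GhmmModel, ModelConfig, TransitionMatrix, uniform_model
from tiergene.states import build_state_set, build_topology

NEG_INF = float("-inf")


def _successors(model: GhmmModel) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for (a, b) in model.transitions.support:
        if a != b:  # runs of self-looping states are merged segments
            out.setdefault(a, []).append(b)
    for k in out:
        out[k].sort()
    return out


def _durations(state, model: GhmmModel, remaining: int) -> list[int]:
    cfg = model.config
    if state.duration_class in ("single_base", "geometric"):
        return list(range(1, remaining + 1))
    if state.category == "donor_site":
        return [cfg.dss_window] if cfg.dss_window <= remaining else []
    if state.category == "acceptor_site":
        return [cfg.ass_window] if cfg.ass_window <= remaining else []
    if state.category == "intron_fixed":
        return [cfg.d] if cfg.d <= remaining else []
    if state.category == "intron_short":
        return list(range(1, min(cfg.d, remaining) + 1))
    lo = model.min_exon_len(state.category)
    return list(range(lo, min(cfg.max_exon_len, remaining) + 1))


def _segment_feasible(seq, model, state, start, end, prev_phase) -> bool:
    """Hard-constraint check (ATG / stop / frame / GT / AG) for one segment;
    used only to prune structurally dead branches during enumeration."""
    from tiergene.emissions import score_segment
    from tiergene.genes import revcomp

    kctx = max(model.config.k, model.config.k_noncoding)
    if state.strand == "forward" or state.category == "intergenic":
        ctx = seq[max(0, start - kctx) : start]
    else:
        ctx = revcomp(seq[end : end + kctx])
    try:
        lp = score_segment(state, seq[start:end], model, entry_phase=prev_phase, context=ctx)
    except ValueError:
        return False
    return lp > NEG_INF


def enumerate_parses(seq: str, model: GhmmModel) -> list[Parse]:
    """All complete legal parses (start and end intergenic) of ``seq``.

    Branches whose newest segment violates a hard biological constraint
    (no ATG, missing GT/AG consensus, broken reading frame, in-frame stop)
    are pruned immediately: they cannot be part of any finite-score parse.
    """
    L = len(seq)
    succ = _successors(model)
    results: list[Parse] = []
    stack: list[Segment] = []

    def rec(pos: int, state_name: str, prev_phase) -> None:
        st = model.state_set[state_name]
        for dur in _durations(st, model, L - pos):
            end = pos + dur
            if not _segment_feasible(seq, model, st, pos, end, prev_phase):
                continue
            stack.append(Segment(state_name, pos, end, 0.0))
            phase = st.phase if st.phase is not None else (None if st.category == "intergenic" else prev_phase)
            if end == L:
                if state_name == "IR":
                    results.append(Parse([Segment(s.state, s.start, s.end, 0.0) for s in stack], 0.0))
            else:
                for nxt in succ.get(state_name, []):
                    rec(end, nxt, phase)
            stack.pop()

    rec(0, "IR", None)
    return results


def best_parse_by_enumeration(seq: str, model: GhmmModel) -> tuple[float, int]:
    """(max log-probability over all legal parses, number of parses)."""
    best = NEG_INF
    parses = enumerate_parses(seq, model)
    for p in parses:
        s = score_fixed_path(seq, p, model)
        if s > best:
            best = s
    return best, len(parses)


def tiny_config(**overrides) -> ModelConfig:
    base = dict(
        k=0,
        k_noncoding=0,
        d=3,
        max_exon_len=12,
        dss_window=2,
        ass_window=2,
        low_t=0.40,
        high_t=0.60,
        length_bandwidth=0,
    )
    base.update(overrides)
    return ModelConfig(**base)


def random_model(rng: np.random.Generator, cfg: ModelConfig | None = None, tiered: bool = True) -> GhmmModel:
    """A fully randomized model on the canonical topology: random stochastic
    transitions and random (normalized) emission/length tables.  Used to make
    optimality and symmetry checks independent of any training code."""
    cfg = cfg or tiny_config()
    m = uniform_model(cfg, tiered=tiered)
    ss = m.state_set
    n = len(ss)
    probs = np.zeros((n, n))
    rows: dict[int, list[int]] = {}
    for (a, b) in build_topology(ss):
        rows.setdefault(ss.ordinal(a), []).append(ss.ordinal(b))
    for ia, outs in rows.items():
        w = rng.random(len(outs)) + 0.05
        if ss[ia].category == "intergenic":
            # keep intergenic sticky so parses are not wall-to-wall genes
            for k, ib in enumerate(outs):
                if ib == ia:
                    w[k] = 30.0 * len(outs)
        w /= w.sum()
        for ib, p in zip(outs, w):
            probs[ia, ib] = p
    m2_trans = TransitionMatrix(ss, probs)

    def rand_log(shape):
        t = rng.random(shape) + 0.1
        t /= t.sum(axis=-1, keepdims=True)
        return np.log(t)

    for key, cm in m._coding.items():
        cm.tables = [rand_log((3, 4 ** o, 4)) for o in range(cfg.k + 1)]
    for hm in (m.ir_model, m.intron_model):
        hm.tables = [rand_log((4 ** o, 4)) for o in range(cfg.k_noncoding + 1)]
    for site in (m.donor_model, m.acceptor_model):
        lp = rand_log((site.width, 4))
        for pos, base in site.consensus.items():
            lp[pos, :] = NEG_INF
            lp[pos, "ACGT".index(base)] = 0.0
        site.log_probs = lp
    for key, ld in m._lengths.items():
        lo = m.min_exon_len(key[0])
        pmf = np.zeros(cfg.max_exon_len)
        pmf[lo - 1 :] = rng.random(cfg.max_exon_len - lo + 1) + 0.1
        pmf /= pmf.sum()
        with np.errstate(divide="ignore"):
            ld.log_pmf = np.log(pmf)
    ipmf = rng.random(cfg.d) + 0.1
    ipmf /= ipmf.sum()
    m.intron_length.log_pmf = np.log(ipmf)
    return GhmmModel(
        ss, m2_trans, m._coding, m._lengths, m.ir_model, m.intron_model,
        m.donor_model, m.acceptor_model, m.intron_length, cfg,
    )


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def plant_gene(rng: np.random.Generator, flank: int = 6) -> str:
    """A short sequence containing a plausible tiny two-exon gene for the
    small-scale decoder tests (tiny windows: donor GT, acceptor AG)."""
    exon1 = "ATG" + random_dna(rng, 3, 0.7)
    exon2 = random_dna(rng, 3, 0.3) + "TAA"
    intron = "GT" + random_dna(rng, 2) + "AG"
    return random_dna(rng, flank, 0.4) + exon1 + intron + exon2 + random_dna(rng, flank, 0.4)
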