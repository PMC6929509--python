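"""Duration-aware Viterbi decoding of genomic sequence into gene structures.

The decoder runs a single left-to-right dynamic program over both strand
halves of the state space.  Explicit-duration states (exons, short introns)
maximize over segment lengths; splice sites and the fixed intron prefix are
fixed-width windows; intergenic and geometric-intron states emit one base
per step.  Reading-frame consistency across introns is enforced through the
phase arithmetic: an exon of length ``l`` entered at phase ``i`` carries
exponent ``(i + l) mod 3`` on the forward strand, and the mirrored rule on
the reverse strand, where decoding order is 3'-to-5' along the transcript.

Biological hard constraints are applied during scoring: initial/single
exons must start with ATG, terminal/single exons must end with a stop
codon, complete in-frame stop codons are forbidden inside coding segments
(except that closing codon), and donor/acceptor windows require GT / AG.

Coordinates are 0-based half-open internally.  The decode starts and must
end in the intergenic state, so only complete genes are reported.  Ties are
broken deterministically (shortest duration, then lowest state ordinal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .emissions import encode, score_segment
from .genes import GeneStructure, revcomp
from .model import GhmmModel

__all__ = ["Segment", "Parse", "viterbi_decode", "path_to_genes", "score_fixed_path"]

NEG_INF = float("-inf")
_BIG = 1 << 30


@dataclass
class Segment:
    state: str
    start: int
    end: int
    log_prob: float  # emission (+ length) contribution of this segment


@dataclass
class Parse:
    segments: list[Segment]
    total_log_prob: float

    def tiles(self, length: int) -> bool:
        pos = 0
        for s in self.segments:
            if s.start != pos or s.end <= s.start:
                return False
            pos = s.end
        return pos == length


def _stop_scan(codes: np.ndarray) -> np.ndarray:
    """Boolean array: a stop codon (TAA/TAG/TGA) starts at t."""
    L = len(codes)
    out = np.zeros(L, dtype=bool)
    if L < 3:
        return out
    c0, c1, c2 = codes[:-2], codes[1:-1], codes[2:]
    is_stop = (c0 == 3) & (((c1 == 0) & ((c2 == 0) | (c2 == 2))) | ((c1 == 2) & (c2 == 0)))
    out[: L - 2] = is_stop
    return out


def _atg_scan(codes: np.ndarray) -> np.ndarray:
    L = len(codes)
    out = np.zeros(L, dtype=bool)
    if L >= 3:
        out[: L - 2] = (codes[:-2] == 0) & (codes[1:-1] == 3) & (codes[2:] == 2)
    return out


def _frame_stop_tables(stop: np.ndarray, L: int):
    """next/prev complete in-frame stop start per frame f (cp = (t+f)%3)."""
    pos = np.arange(L)
    nxt, prv = [], []
    for f in range(3):
        inframe = stop & ((pos + f) % 3 == 0)
        idx = np.where(inframe, pos, _BIG)
        nx = np.minimum.accumulate(idx[::-1])[::-1]
        nx = np.concatenate([nx, np.full(2, _BIG, dtype=np.int64)])  # valid at t in [0, L+1]
        pidx = np.where(inframe, pos, -1)
        pv = np.maximum.accumulate(pidx)
        pv = np.concatenate([pv, np.full(2, pv[-1] if L else -1, dtype=np.int64)])
        nxt.append(nx)
        prv.append(pv)
    return nxt, prv


class _Precomp:
    """Per-sequence emission arrays shared by all DP cells."""

    def __init__(self, seq: str, model: GhmmModel):
        self.L = L = len(seq)
        self.codes = encode(seq)
        self.rc_codes = encode(revcomp(seq))
        self.ir = model.ir_model.position_scores(self.codes)
        intron_f = model.intron_model.position_scores(self.codes)
        intron_r = model.intron_model.position_scores(self.rc_codes)
        self.intron_f = intron_f
        self.intron_r = intron_r
        self.cum_intron_f = np.concatenate([[0.0], np.cumsum(intron_f)])
        self.cum_intron_r = np.concatenate([[0.0], np.cumsum(intron_r)])

        def padded(site_scores: np.ndarray) -> np.ndarray:
            out = np.full(L + 1, NEG_INF)
            out[: len(site_scores)] = site_scores
            return out

        self.dss_f = padded(model.donor_model.window_scores(self.codes))
        self.dss_r = padded(model.donor_model.window_scores(self.rc_codes))
        self.ass_f = padded(model.acceptor_model.window_scores(self.codes))
        self.ass_r = padded(model.acceptor_model.window_scores(self.rc_codes))

        self.atg_f = _atg_scan(self.codes)
        self.atg_r = _atg_scan(self.rc_codes)
        stop_f = _stop_scan(self.codes)
        stop_r = _stop_scan(self.rc_codes)
        self.next_stop_f, self.prev_stop_f = _frame_stop_tables(stop_f, L)
        self.next_stop_r, self.prev_stop_r = _frame_stop_tables(stop_r, L)
        self.stop_at_f = [stop_f & ((np.arange(L) + f) % 3 == 0) for f in range(3)]

        self._exon_cum: dict = {}
        self._model = model

    def exon_cum(self, category: str, tier, frame: int, strand: str) -> np.ndarray:
        """Cumulative coding log-prob array for one emission model/frame."""
        m = self._model.coding_model(category, tier)
        key = (id(m), frame, strand)
        if key not in self._exon_cum:
            codes = self.codes if strand == "forward" else self.rc_codes
            lp = m.position_scores(codes, frame)
            self._exon_cum[key] = np.concatenate([[0.0], np.cumsum(lp)])
        return self._exon_cum[key]


def viterbi_decode(seq: str, model: GhmmModel) -> Parse:
    """Most probable complete parse of ``seq`` under the model."""
    L = len(seq)
    if L < 1:
        raise ValueError("cannot decode an empty sequence")
    ss = model.state_set
    cfg = model.config
    n = len(ss)
    logA = model.transitions.log_probs
    pre = _Precomp(seq, model)

    delta = np.full((L + 1, n), NEG_INF)
    bp_state = np.full((L + 1, n), -1, dtype=np.int32)
    bp_len = np.zeros((L + 1, n), dtype=np.int32)

    ir = ss.ordinal("IR")
    tiers = ("high", "medium", "low") if ss.tiered else (None,)
    suf = {"high": "_H", "medium": "_M", "low": "_L", None: ""}

    def nm(base: str, t) -> str:
        return base + suf[t]

    ir_preds = [ir] + [
        ss.ordinal(nm(b, t))
        for b in ("E_single", "E_term", "rE_single", "rE_init")
        for t in tiers
    ]
    ir_preds = np.array(sorted(ir_preds), dtype=np.int64)

    exon_states = []  # (ordinal, State, min_len)
    for s in ss:
        if s.is_exon:
            exon_states.append((ss.ordinal(s.name), s, model.min_exon_len(s.category)))

    ishort_lp = model.intron_length.log_pmf
    len_lp = {
        (c, t): model.length_distribution(c, t).log_pmf
        for c in ("exon_single", "exon_initial", "exon_internal", "exon_terminal")
        for t in tiers
    }

    Wd, Wa, d = cfg.dss_window, cfg.ass_window, cfg.d

    def set_cell(j: int, si: int, vals: np.ndarray, s_arr: np.ndarray, pred_ord) -> None:
        """Pick the best candidate; prefer the largest s (shortest duration)."""
        if len(vals) == 0:
            return
        rev = vals[::-1]
        k = int(np.argmax(rev))
        v = rev[k]
        if v == NEG_INF:
            return
        s_best = int(s_arr[::-1][k])
        delta[j, si] = v
        bp_len[j, si] = j - s_best
        if np.isscalar(pred_ord) or isinstance(pred_ord, (int, np.integer)):
            bp_state[j, si] = int(pred_ord)
        else:
            bp_state[j, si] = int(pred_ord[::-1][k])

    for j in range(1, L + 1):
        # --- intergenic (single base) ---
        if j == 1:
            delta[1, ir] = pre.ir[0]  # initial distribution: start in IR
            bp_state[1, ir] = -1
            bp_len[1, ir] = 1
        else:
            cand = delta[j - 1, ir_preds] + logA[ir_preds, ir]
            k = int(np.argmax(cand))
            if cand[k] > NEG_INF:
                delta[j, ir] = cand[k] + pre.ir[j - 1]
                bp_state[j, ir] = int(ir_preds[k])
                bp_len[j, ir] = 1

        for x in range(3):
            # --- forward splice/intron chain ---
            dss = ss.ordinal(f"DSS_{x}")
            s0 = j - Wd
            if s0 >= 1:
                preds = [ss.ordinal(nm(f"E_init_{x}", t)) for t in tiers] + [
                    ss.ordinal(nm(f"E_int_{x}", t)) for t in tiers
                ]
                preds = np.array(preds, dtype=np.int64)
                cand = delta[s0, preds] + logA[preds, dss]
                k = int(np.argmax(cand))
                if cand[k] > NEG_INF and pre.dss_f[s0] > NEG_INF:
                    delta[j, dss] = cand[k] + pre.dss_f[s0]
                    bp_state[j, dss] = int(preds[k])
                    bp_len[j, dss] = Wd

            isrt = ss.ordinal(f"I_short_{x}")
            s_lo = max(1, j - d)
            if s_lo <= j - 1:
                s_arr = np.arange(s_lo, j)
                vals = (
                    delta[s_arr, dss]
                    + logA[dss, isrt]
                    + (pre.cum_intron_f[j] - pre.cum_intron_f[s_arr])
                    + ishort_lp[j - s_arr - 1]
                )
                set_cell(j, isrt, vals, s_arr, dss)

            ifx = ss.ordinal(f"I_fixed_{x}")
            s0 = j - d
            if s0 >= 1 and delta[s0, dss] > NEG_INF:
                v = delta[s0, dss] + logA[dss, ifx] + pre.cum_intron_f[j] - pre.cum_intron_f[s0]
                if v > delta[j, ifx]:
                    delta[j, ifx] = v
                    bp_state[j, ifx] = dss
                    bp_len[j, ifx] = d

            igeo = ss.ordinal(f"I_geo_{x}")
            c_fix = delta[j - 1, ifx] + logA[ifx, igeo]
            c_self = delta[j - 1, igeo] + logA[igeo, igeo]
            best, pred = (c_self, igeo) if c_self >= c_fix else (c_fix, ifx)
            if best > NEG_INF:
                delta[j, igeo] = best + pre.intron_f[j - 1]
                bp_state[j, igeo] = pred
                bp_len[j, igeo] = 1

            ass = ss.ordinal(f"ASS_{x}")
            s0 = j - Wa
            if s0 >= 1 and pre.ass_f[s0] > NEG_INF:
                c1 = delta[s0, isrt] + logA[isrt, ass]
                c2 = delta[s0, igeo] + logA[igeo, ass]
                best, pred = (c1, isrt) if c1 >= c2 else (c2, igeo)
                if best > NEG_INF:
                    delta[j, ass] = best + pre.ass_f[s0]
                    bp_state[j, ass] = pred
                    bp_len[j, ass] = Wa

            # --- reverse splice/intron chain (genomic order: rASS .. rDSS) ---
            rass = ss.ordinal(f"rASS_{x}")
            s0 = j - Wa
            if s0 >= 1 and pre.ass_r[L - j] > NEG_INF:
                preds = [ss.ordinal(nm(f"rE_term_{x}", t)) for t in tiers] + [
                    ss.ordinal(nm(f"rE_int_{x}", t)) for t in tiers
                ]
                preds = np.array(preds, dtype=np.int64)
                cand = delta[s0, preds] + logA[preds, rass]
                k = int(np.argmax(cand))
                if cand[k] > NEG_INF:
                    delta[j, rass] = cand[k] + pre.ass_r[L - j]
                    bp_state[j, rass] = int(preds[k])
                    bp_len[j, rass] = Wa

            rsrt = ss.ordinal(f"rI_short_{x}")
            s_lo = max(1, j - d)
            if s_lo <= j - 1:
                s_arr = np.arange(s_lo, j)
                vals = (
                    delta[s_arr, rass]
                    + logA[rass, rsrt]
                    + (pre.cum_intron_r[L - s_arr] - pre.cum_intron_r[L - j])
                    + ishort_lp[j - s_arr - 1]
                )
                set_cell(j, rsrt, vals, s_arr, rass)

            rfx = ss.ordinal(f"rI_fixed_{x}")
            s0 = j - d
            if s0 >= 1 and delta[s0, rass] > NEG_INF:
                v = (
                    delta[s0, rass]
                    + logA[rass, rfx]
                    + pre.cum_intron_r[L - s0]
                    - pre.cum_intron_r[L - j]
                )
                if v > delta[j, rfx]:
                    delta[j, rfx] = v
                    bp_state[j, rfx] = rass
                    bp_len[j, rfx] = d

            rgeo = ss.ordinal(f"rI_geo_{x}")
            c_fix = delta[j - 1, rfx] + logA[rfx, rgeo]
            c_self = delta[j - 1, rgeo] + logA[rgeo, rgeo]
            best, pred = (c_self, rgeo) if c_self >= c_fix else (c_fix, rfx)
            if best > NEG_INF:
                delta[j, rgeo] = best + pre.intron_r[L - j]
                bp_state[j, rgeo] = pred
                bp_len[j, rgeo] = 1

            rdss = ss.ordinal(f"rDSS_{x}")
            s0 = j - Wd
            if s0 >= 1 and pre.dss_r[L - j] > NEG_INF:
                c1 = delta[s0, rsrt] + logA[rsrt, rdss]
                c2 = delta[s0, rgeo] + logA[rgeo, rdss]
                best, pred = (c1, rsrt) if c1 >= c2 else (c2, rgeo)
                if best > NEG_INF:
                    delta[j, rdss] = best + pre.dss_r[L - j]
                    bp_state[j, rdss] = pred
                    bp_len[j, rdss] = Wd

        # --- exon states ---
        for si, st, min_len in exon_states:
            cat, tier, strand = st.category, st.gc_tier, st.strand
            s_min = max(0, j - cfg.max_exon_len)
            s_max = j - min_len
            if s_max < s_min:
                continue

            if strand == "forward":
                if cat == "exon_initial":
                    f = (st.phase - j) % 3
                elif cat == "exon_internal":
                    f = (st.phase - j) % 3
                else:  # single / terminal close the frame at j
                    f = (-j) % 3
                cum = pre.exon_cum(cat, tier, f, "forward")
                if cat in ("exon_single", "exon_terminal"):
                    if j < 3 or not pre.stop_at_f[f][j - 3]:
                        continue
                    s_min = max(s_min, int(pre.prev_stop_f[f][j - 4]) + 1 if j >= 4 else 0)
                    s_max = min(s_max, j - 3)
                else:
                    s_min = max(s_min, int(pre.prev_stop_f[f][j - 3]) + 1 if j >= 3 else 0)

                if cat in ("exon_single", "exon_initial"):
                    step = 3
                    rem = (j - (st.phase or 0)) % 3 if cat == "exon_initial" else j % 3
                    lo = s_min + ((rem - s_min) % 3)
                    s_arr = np.arange(lo, s_max + 1, step)
                    if len(s_arr) == 0:
                        continue
                    s_arr = s_arr[pre.atg_f[s_arr]]
                    if len(s_arr) == 0:
                        continue
                    ent = delta[s_arr, ir] + logA[ir, si]
                    pred_ord = ir
                else:
                    s_arr = np.arange(s_min, s_max + 1)
                    if len(s_arr) == 0:
                        continue
                    ent = np.full(len(s_arr), NEG_INF)
                    pred_ord = np.full(len(s_arr), -1, dtype=np.int64)
                    for m in range(3):
                        sel = (s_arr % 3) == m
                        if not sel.any():
                            continue
                        if cat == "exon_internal":
                            x = (st.phase - j + m) % 3
                        else:  # terminal: (0 - l) mod 3 with l = j - s
                            x = (m - j) % 3
                        p = ss.ordinal(f"ASS_{x}")
                        ent[sel] = delta[s_arr[sel], p] + logA[p, si]
                        pred_ord[sel] = p
                vals = ent + (cum[j] - cum[s_arr]) + len_lp[(cat, tier)][j - s_arr - 1]
                set_cell(j, si, vals, s_arr, pred_ord)

            else:  # reverse strand: rc segment is [L-j, L-s)
                sp = L - j  # rc start, fixed for this j
                if cat in ("exon_initial", "exon_single"):
                    c0 = 0
                else:
                    c0 = st.phase
                f = (c0 - sp) % 3
                cum = pre.exon_cum(cat, tier, f, "reverse")

                if cat in ("exon_single", "exon_initial") and not pre.atg_r[sp]:
                    continue

                if cat in ("exon_single", "exon_terminal"):
                    # the closing stop fixes the duration: first in-frame stop
                    p_stop = int(pre.next_stop_r[f][sp])
                    if p_stop >= _BIG:
                        continue
                    e_rc = p_stop + 3
                    s = L - e_rc
                    if s < s_min or s > s_max:
                        continue
                    s_arr = np.array([s])
                else:
                    e_max_rc = int(pre.next_stop_r[f][sp]) + 2
                    s_lo = max(s_min, L - e_max_rc)
                    s_arr = np.arange(s_lo, s_max + 1)
                    if len(s_arr) == 0:
                        continue

                if cat in ("exon_single", "exon_terminal"):
                    if cat == "exon_terminal" and (j - s_arr[0] + st.phase) % 3 != 0:
                        continue  # guard; the frame arithmetic normally ensures this
                    ent = delta[s_arr, ir] + logA[ir, si]
                    pred_ord = ir
                else:
                    ent = np.full(len(s_arr), NEG_INF)
                    pred_ord = np.full(len(s_arr), -1, dtype=np.int64)
                    for m in range(3):
                        sel = (s_arr % 3) == m
                        if not sel.any():
                            continue
                        if cat == "exon_internal":
                            x = (st.phase + j - m) % 3
                        else:  # rE_init: l mod 3 = (j - s) mod 3
                            x = (j - m) % 3
                        p = ss.ordinal(f"rDSS_{x}")
                        ent[sel] = delta[s_arr[sel], p] + logA[p, si]
                        pred_ord[sel] = p
                vals = ent + (cum[L - s_arr] - cum[sp]) + len_lp[(cat, tier)][j - s_arr - 1]
                set_cell(j, si, vals, s_arr, pred_ord)

    # --- backtrack from (L, IR): parses must end intergenic ---
    if delta[L, ir] == NEG_INF:
        raise RuntimeError("no parse ending in the intergenic state (unexpected)")
    segs: list[Segment] = []
    j, si = L, ir
    while j > 0:
        ln = int(bp_len[j, si])
        pred = int(bp_state[j, si])
        segs.append(Segment(ss[si].name, j - ln, j, 0.0))
        j -= ln
        if pred < 0:
            break
        si = pred
    segs.reverse()
    merged: list[Segment] = []
    for s in segs:
        same_run = (
            merged
            and merged[-1].state == s.state
            and ss[s.state].duration_class in ("single_base", "geometric")
        )
        if same_run:
            merged[-1] = Segment(s.state, merged[-1].start, s.end, 0.0)
        else:
            merged.append(Segment(s.state, s.start, s.end, 0.0))
    total = float(delta[L, ir])
    parse = Parse(merged, total)
    _fill_segment_scores(seq, parse, model)
    return parse


def _fill_segment_scores(seq: str, parse: Parse, model: GhmmModel) -> None:
    """Populate per-segment emission contributions via the reference scorer."""
    ss = model.state_set
    kctx = max(model.config.k, model.config.k_noncoding)
    prev_phase: int | None = None
    for seg in parse.segments:
        st = ss[seg.state]
        if st.strand == "forward" or st.category == "intergenic":
            if st.category == "intergenic" and model.ir_model.direction == "right":
                ctx = seq[seg.end : seg.end + kctx]
            else:
                ctx = seq[max(0, seg.start - kctx) : seg.start]
        else:
            ctx = revcomp(seq[seg.end : seg.end + kctx])
        try:
            seg.log_prob = score_segment(
                st, seq[seg.start : seg.end], model, entry_phase=prev_phase, context=ctx
            )
        except ValueError:
            seg.log_prob = NEG_INF
        if st.phase is not None:
            prev_phase = st.phase
        elif st.category == "intergenic":
            prev_phase = None


def path_to_genes(parse: Parse, seqid: str = "seq") -> list[GeneStructure]:
    """Convert a parse into gene structures: each maximal run of gene states
    between intergenic segments becomes one gene."""
    genes: list[GeneStructure] = []
    run: list[Segment] = []
    counter = 0
    for seg in list(parse.segments) + [Segment("IR", -1, -1, 0.0)]:
        if seg.state == "IR":
            if run:
                counter += 1
                genes.append(_run_to_gene(run, seqid, f"{seqid}.g{counter}"))
                run = []
        else:
            run.append(seg)
    return genes


_TIER_BY_SUFFIX = {"H": "high", "M": "medium", "L": "low"}


def _state_fields(name: str) -> tuple[str, int | None, str | None, str]:
    """(category, phase, tier, strand) parsed back from a state name."""
    strand = "reverse" if name.startswith("r") else "forward"
    core = name[1:] if strand == "reverse" else name
    tier = None
    if core[-2:] in ("_H", "_M", "_L"):
        tier = _TIER_BY_SUFFIX[core[-1]]
        core = core[:-2]
    phase = None
    if core[-1].isdigit():
        phase = int(core[-1])
        core = core[:-2]  # strip "_<digit>"
    cat = {
        "E_single": "exon_single",
        "E_init": "exon_initial",
        "E_int": "exon_internal",
        "E_term": "exon_terminal",
        "DSS": "donor_site",
        "ASS": "acceptor_site",
        "I_short": "intron_short",
        "I_fixed": "intron_fixed",
        "I_geo": "intron_geometric",
    }[core]
    return cat, phase, tier, strand


def _run_to_gene(run: list[Segment], seqid: str, gene_id: str) -> GeneStructure:
    exons: list[tuple[int, int]] = []
    labels: list[tuple[str, int | None, str | None]] = []
    strand = None
    prev_end = None
    for seg in run:
        cat, phase, tier, st_strand = _state_fields(seg.state)
        if prev_end is not None and seg.start != prev_end:
            raise ValueError("malformed parse: gene segments do not tile")
        prev_end = seg.end
        if strand is None:
            strand = st_strand
        elif strand != st_strand:
            raise ValueError("malformed parse: mixed strands inside one gene run")
        if cat.startswith("exon"):
            exons.append((seg.start, seg.end))
            labels.append((cat, phase, tier))
    if not exons:
        raise ValueError("malformed parse: gene run without exon segments")
    return GeneStructure(gene_id, seqid, strand, exons, labels)


def score_fixed_path(seq: str, parse: Parse, model: GhmmModel) -> float:
    """Joint log-probability of a given parse by explicit summation,
    independent of the dynamic program: initial term, transition terms
    (including the per-base self-loops of intergenic and geometric-intron
    runs) and per-segment emission terms."""
    if not parse.tiles(len(seq)):
        raise ValueError("parse does not tile the sequence")
    ss = model.state_set
    logA = model.transitions.log_probs
    kctx = max(model.config.k, model.config.k_noncoding)
    total = 0.0
    prev: str | None = None
    prev_phase: int | None = None
    for seg in parse.segments:
        st = ss[seg.state]
        if prev is None:
            if seg.state != "IR":
                return NEG_INF  # initial distribution: IR with probability 1
        else:
            if (prev, seg.state) not in model.transitions.support:
                return NEG_INF
            total += logA[ss.ordinal(prev), ss.ordinal(seg.state)]
        if st.duration_class in ("single_base", "geometric"):
            n_loops = (seg.end - seg.start) - 1
            self_lp = logA[ss.ordinal(seg.state), ss.ordinal(seg.state)]
            if n_loops > 0 and self_lp == NEG_INF:
                return NEG_INF
            total += n_loops * self_lp
        if st.strand == "forward" or st.category == "intergenic":
            if st.category == "intergenic" and model.ir_model.direction == "right":
                ctx = seq[seg.end : seg.end + kctx]
            else:
                ctx = seq[max(0, seg.start - kctx) : seg.start]
        else:
            ctx = revcomp(seq[seg.end : seg.end + kctx])
        try:
            emis = score_segment(
                st, seq[seg.start : seg.end], model, entry_phase=prev_phase, context=ctx
            )
        except ValueError:
            return NEG_INF
        total += emis
        if total == NEG_INF:
            return NEG_INF
        if st.phase is not None:
            prev_phase = st.phase
        elif st.category == "intergenic":
            prev_phase = None
        prev = seg.state
    return float(total)
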