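"""Per-state emission models and exon length distributions.

Coding exons are scored by inhomogeneous k-th order Markov chains (one
conditional table per codon position, default k=4) with lower-order
fallback tables for positions whose left context is truncated by a
sequence boundary or an ambiguous base.  Introns and intergenic sequence
use homogeneous chains; splice sites use fixed-length positional weight
matrices with hard GT / AG consensus positions.  Explicit-duration exon
states additionally carry a smoothed empirical length distribution.

All probabilities are handled in natural-log space.  ``N`` bases emit with
probability 1/4 from every state and truncate Markov contexts.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .genes import STOP_CODONS, revcomp
from .states import State

__all__ = [
    "CodingMarkovModel",
    "HomogeneousMarkovModel",
    "SiteWindowModel",
    "LengthDistribution",
    "fit_coding_markov",
    "fit_homogeneous_markov",
    "fit_site_window",
    "fit_length_distribution",
    "score_segment",
    "encode",
]

LOG_QUARTER = math.log(0.25)
NEG_INF = float("-inf")

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _avail_left(codes: np.ndarray, k: int) -> np.ndarray:
    """Usable left-context length at each position (capped at k):
    the number of contiguous non-N bases immediately preceding it."""
    L = len(codes)
    pos = np.arange(L)
    marks = np.where(codes == 4, pos, -1)
    last_n = np.maximum.accumulate(marks)
    last_n_before = np.concatenate(([-1], last_n[:-1]))
    return np.minimum(k, pos - 1 - last_n_before)


def _avail_right(codes: np.ndarray, k: int) -> np.ndarray:
    return _avail_left(codes[::-1], k)[::-1]


def _ctx_index(codes: np.ndarray, order: int, direction: str) -> np.ndarray:
    """Base-4 context index per position; nearest context base is the
    lowest digit.  Positions with insufficient context hold garbage and
    must be masked by the caller."""
    L = len(codes)
    idx = np.zeros(L, dtype=np.int64)
    c = (codes % 4).astype(np.int64)
    for m in range(1, order + 1):
        shifted = np.empty(L, dtype=np.int64)
        if direction == "left":
            shifted[:m] = 0
            shifted[m:] = c[:-m] if m else c
        else:
            shifted[L - m :] = 0
            shifted[: L - m] = c[m:]
        idx += shifted * (4 ** (m - 1))
    return idx


def _positional_logprob(
    tables: list[np.ndarray],
    codes: np.ndarray,
    k: int,
    direction: str = "left",
    cp: np.ndarray | None = None,
) -> np.ndarray:
    """Per-position emission log-probability with boundary/N backoff.

    ``tables[o]`` has shape (4**o, 4) or, when ``cp`` is given, (3, 4**o, 4).
    """
    L = len(codes)
    out = np.full(L, LOG_QUARTER)
    if L == 0:
        return out
    avail = _avail_left(codes, k) if direction == "left" else _avail_right(codes, k)
    base_ok = codes < 4
    for o in range(k + 1):
        mask = base_ok & (avail == o) if o < k else base_ok & (avail >= k)
        if not mask.any():
            continue
        idx = _ctx_index(codes, o, direction)[mask]
        b = codes[mask].astype(np.int64)
        if cp is None:
            out[mask] = tables[o][idx, b]
        else:
            out[mask] = tables[o][cp[mask], idx, b]
    return out


class CodingMarkovModel:
    """Inhomogeneous k-th order Markov chain over coding sequence.

    One conditional distribution per (codon position, k-mer context), plus
    fallback tables of orders k-1 .. 0 used where the context is truncated.
    """

    def __init__(self, k: int, tables: list[np.ndarray]):
        self.k = k
        self.tables = tables  # tables[o]: (3, 4**o, 4) log-probs

    def position_scores(self, codes: np.ndarray, frame: int) -> np.ndarray:
        """log P(base_t | left context, codon position (t + frame) mod 3)."""
        cp = (np.arange(len(codes)) + frame) % 3
        return _positional_logprob(self.tables, codes, self.k, "left", cp)

    def score(self, seq: str, cp0: int, context: str = "") -> float:
        codes = encode(context + seq)
        frame = (cp0 - len(context)) % 3
        return float(self.position_scores(codes, frame)[len(context):].sum())

    def to_dict(self) -> dict:
        return {"k": self.k, "tables": [t.tolist() for t in self.tables]}

    @classmethod
    def from_dict(cls, d: dict) -> "CodingMarkovModel":
        return cls(d["k"], [np.asarray(t, dtype=float) for t in d["tables"]])


class HomogeneousMarkovModel:
    """Homogeneous k-th order Markov chain (introns, intergenic).

    ``direction`` is "left" for the usual 5'-to-3' conditional chain; the
    reverse-complement mirror (used when strand-mirroring a model) is a
    "right"-direction chain conditioning on the following bases.
    """

    def __init__(self, k: int, tables: list[np.ndarray], direction: str = "left"):
        self.k = k
        self.tables = tables  # tables[o]: (4**o, 4) log-probs
        self.direction = direction

    def position_scores(self, codes: np.ndarray) -> np.ndarray:
        return _positional_logprob(self.tables, codes, self.k, self.direction)

    def score(self, seq: str, context: str = "") -> float:
        if self.direction == "left":
            codes = encode(context + seq)
            return float(self.position_scores(codes)[len(context):].sum())
        codes = encode(seq + context)
        return float(self.position_scores(codes)[: len(seq)].sum())

    def rc_mirror(self) -> "HomogeneousMarkovModel":
        """The model scoring x exactly as this model scores revcomp(x)."""
        new_tables = []
        for o, tab in enumerate(self.tables):
            nt = np.empty_like(tab)
            for ctx in range(4 ** o):
                digits = [(ctx // 4 ** m) % 4 for m in range(o)]
                cctx = sum((3 - d) * 4 ** m for m, d in enumerate(digits))
                nt[ctx, :] = tab[cctx, ::-1]
            new_tables.append(nt)
        return HomogeneousMarkovModel(
            self.k, new_tables, "right" if self.direction == "left" else "left"
        )

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "direction": self.direction,
            "tables": [t.tolist() for t in self.tables],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HomogeneousMarkovModel":
        return cls(d["k"], [np.asarray(t, dtype=float) for t in d["tables"]], d["direction"])


class SiteWindowModel:
    """Fixed-width positional model for a splice-site window.

    ``consensus`` maps window offsets to mandatory bases (e.g. the GT of a
    donor site); a mismatch there scores -inf (hard constraint).
    """

    def __init__(self, width: int, log_probs: np.ndarray, consensus: dict[int, str]):
        self.width = width
        self.log_probs = log_probs  # (width, 4)
        self.consensus = dict(consensus)

    def window_scores(self, codes: np.ndarray) -> np.ndarray:
        """Score of the window starting at each position (length L-W+1)."""
        L = len(codes)
        W = self.width
        n = L - W + 1
        if n <= 0:
            return np.empty(0)
        out = np.zeros(n)
        for w in range(W):
            b = codes[w : w + n]
            col = np.where(b < 4, self.log_probs[w][np.minimum(b, 3)], LOG_QUARTER)
            if w in self.consensus:
                need = encode(self.consensus[w])[0]
                col = np.where(b == need, col, NEG_INF)
            out += col
        return out

    def score(self, seq: str) -> float:
        if len(seq) != self.width:
            raise ValueError(f"window of length {len(seq)} for model of width {self.width}")
        return float(self.window_scores(encode(seq))[0])

    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "log_probs": self.log_probs.tolist(),
            "consensus": {str(k): v for k, v in self.consensus.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SiteWindowModel":
        return cls(
            d["width"],
            np.asarray(d["log_probs"], dtype=float),
            {int(k): v for k, v in d["consensus"].items()},
        )


class LengthDistribution:
    """Probability mass over segment lengths 1..max_len."""

    def __init__(self, log_pmf: np.ndarray):
        self.log_pmf = log_pmf  # index l-1 holds log P(length = l)

    @property
    def max_len(self) -> int:
        return len(self.log_pmf)

    def logp(self, length: int) -> float:
        if 1 <= length <= self.max_len:
            return float(self.log_pmf[length - 1])
        return NEG_INF

    def pmf(self) -> np.ndarray:
        return np.exp(self.log_pmf)

    def mean(self) -> float:
        return float((np.arange(1, self.max_len + 1) * self.pmf()).sum())

    def to_dict(self) -> dict:
        return {"log_pmf": self.log_pmf.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "LengthDistribution":
        return cls(np.asarray(d["log_pmf"], dtype=float))


def _concat_for_fit(
    seqs: list,
    coding: bool,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Concatenate training sequences with N separators.

    Items are (seq,) / (seq, cp0) / (seq, cp0, context).  Context bases are
    included for conditioning but masked out of the event counts.  Returns
    (codes, codon positions or None, count mask).
    """
    parts, cps, masks = [], [], []
    for item in seqs:
        if isinstance(item, str):
            seq, cp0, context = item, 0, ""
        elif len(item) == 2:
            (seq, cp0), context = item, ""
        else:
            seq, cp0, context = item
        full = context + seq + "N"
        parts.append(full)
        if coding:
            cp = (np.arange(len(full)) + cp0 - len(context)) % 3
            cps.append(cp)
        m = np.zeros(len(full), dtype=bool)
        m[len(context) : len(context) + len(seq)] = True
        masks.append(m)
    codes = encode("".join(parts))
    cp_all = np.concatenate(cps) if coding else None
    return codes, cp_all, np.concatenate(masks)


def _fit_markov_counts(
    codes: np.ndarray,
    mask: np.ndarray,
    k: int,
    cp: np.ndarray | None,
) -> list[np.ndarray]:
    """Add-one-smoothed conditional log tables for orders 0..k.

    Every counted position contributes to its usable order and to all lower
    orders, so the fallback tables are fitted simultaneously.
    """
    avail = _avail_left(codes, k)
    base_ok = mask & (codes < 4)
    tables = []
    for o in range(k + 1):
        shape = (3, 4 ** o, 4) if cp is not None else (4 ** o, 4)
        counts = np.zeros(shape)
        sel = base_ok & (avail >= o)
        if sel.any():
            idx = _ctx_index(codes, o, "left")[sel]
            b = codes[sel].astype(np.int64)
            if cp is not None:
                flat = (cp[sel] * (4 ** o) + idx) * 4 + b
                counts = np.bincount(flat, minlength=3 * 4 ** o * 4).reshape(shape).astype(float)
            else:
                flat = idx * 4 + b
                counts = np.bincount(flat, minlength=4 ** o * 4).reshape(shape).astype(float)
        counts += 1.0  # add-one smoothing
        tables.append(np.log(counts / counts.sum(axis=-1, keepdims=True)))
    return tables


def fit_coding_markov(exon_seqs: list, k: int) -> CodingMarkovModel:
    """Fit the inhomogeneous coding chain from (sequence, start codon
    position[, upstream context]) items.  Empty input yields a uniform
    model with a warning."""
    if k < 0:
        raise ValueError("order k must be >= 0")
    if not exon_seqs:
        warnings.warn("empty coding training set; using a uniform model")
        tables = [np.full((3, 4 ** o, 4), LOG_QUARTER) for o in range(k + 1)]
        return CodingMarkovModel(k, tables)
    codes, cp, mask = _concat_for_fit(exon_seqs, coding=True)
    return CodingMarkovModel(k, _fit_markov_counts(codes, mask, k, cp))


def fit_homogeneous_markov(seqs: list, k: int) -> HomogeneousMarkovModel:
    if not seqs:
        warnings.warn("empty noncoding training set; using a uniform model")
        return HomogeneousMarkovModel(k, [np.full((4 ** o, 4), LOG_QUARTER) for o in range(k + 1)])
    items = [(s, 0, "") if isinstance(s, str) else s for s in seqs]
    codes, _, mask = _concat_for_fit(items, coding=False)
    return HomogeneousMarkovModel(k, _fit_markov_counts(codes, mask, k, None))


def fit_site_window(
    windows: list[str], width: int, consensus: dict[int, str]
) -> SiteWindowModel:
    """Fit per-position base distributions; consensus positions are fixed
    to probability one on the consensus base."""
    counts = np.ones((width, 4))
    for w in windows:
        if len(w) != width:
            raise ValueError("window of wrong width in training data")
        c = encode(w)
        for pos in range(width):
            if c[pos] < 4:
                counts[pos, c[pos]] += 1
    lp = np.log(counts / counts.sum(axis=1, keepdims=True))
    for pos, base in consensus.items():
        lp[pos, :] = NEG_INF
        lp[pos, encode(base)[0]] = 0.0
    return SiteWindowModel(width, lp, consensus)


def fit_length_distribution(
    lengths: list[int], max_len: int, smoothing_bandwidth: int = 10
) -> LengthDistribution:
    """Empirical histogram smoothed with a triangular kernel and
    renormalized over [1, max_len].  Lengths above the cap are clamped
    with a warning."""
    if not lengths:
        raise ValueError("cannot fit a length distribution from no lengths")
    if any(l < 1 for l in lengths):
        raise ValueError("lengths must be positive")
    arr = np.asarray(lengths, dtype=np.int64)
    if (arr > max_len).any():
        warnings.warn(f"{int((arr > max_len).sum())} length(s) above cap {max_len}; clamped")
        arr = np.minimum(arr, max_len)
    hist = np.bincount(arr, minlength=max_len + 1)[1:].astype(float)
    bw = int(smoothing_bandwidth)
    if bw > 0:
        kern = np.array([bw + 1 - abs(d) for d in range(-bw, bw + 1)], dtype=float)
        kern /= kern.sum()
        hist = np.convolve(hist, kern, mode="same")
    tot = hist.sum()
    if tot <= 0:
        raise ValueError("degenerate length histogram")
    pmf = hist / tot
    with np.errstate(divide="ignore"):
        return LengthDistribution(np.log(pmf))


def _coding_constraint_violations(cds: str, role: str) -> bool:
    """True if the transcript-orientation exon sequence violates a hard
    coding constraint for its role (read at codon position 0 start)."""
    if role in ("exon_single", "exon_initial") and not cds.upper().startswith("ATG"):
        return True
    up = cds.upper()
    if role in ("exon_single", "exon_terminal"):
        if up[-3:] not in STOP_CODONS:
            return True
    return False


def score_segment(
    state: State,
    seq: str,
    model,
    entry_phase: int | None = None,
    context: str = "",
    enforce_constraints: bool = True,
) -> float:
    """Reference (non-vectorized) emission score of one segment.

    ``seq`` is the genomic forward-strand segment; reverse-strand states
    score its reverse complement.  ``context`` is the up-to-k bases
    preceding the segment in the state's reading direction (transcript
    order for gene states), already reverse-complemented for reverse-strand
    states.  For exon and short-intron states the score includes the length
    log-probability.  Used by the independent path re-scorer and by tests;
    the Viterbi decoder computes the same quantities from precomputed
    arrays.
    """
    from .model import GhmmModel  # local import to avoid a cycle

    assert isinstance(model, GhmmModel)
    cfg = model.config
    name, cat = state.name, state.category
    L = len(seq)

    if cat == "intergenic":
        return model.ir_model.score(seq, context=context)

    if cat in ("donor_site", "acceptor_site", "intron_fixed"):
        widths = {
            "donor_site": cfg.dss_window,
            "acceptor_site": cfg.ass_window,
            "intron_fixed": cfg.d,
        }
        if L != widths[cat]:
            raise ValueError(f"{name}: segment length {L} != fixed window {widths[cat]}")
        oriented = seq if state.strand == "forward" else revcomp(seq)
        if cat == "intron_fixed":
            return model.intron_model.score(oriented, context=context)
        site = model.donor_model if cat == "donor_site" else model.acceptor_model
        return site.score(oriented)

    if cat == "intron_geometric":
        oriented = seq if state.strand == "forward" else revcomp(seq)
        return model.intron_model.score(oriented, context=context)

    if cat == "intron_short":
        if not 1 <= L <= cfg.d:
            raise ValueError(f"{name}: short-intron length {L} outside [1, {cfg.d}]")
        oriented = seq if state.strand == "forward" else revcomp(seq)
        return model.intron_length.logp(L) + model.intron_model.score(oriented, context=context)

    # exon states
    if state.strand == "forward":
        cds = seq
        if cat in ("exon_single", "exon_initial"):
            c0 = 0
        else:
            if entry_phase is None:
                raise ValueError(f"{name}: entry_phase required")
            c0 = entry_phase
        if cat == "exon_single" and L % 3 != 0:
            raise ValueError(f"{name}: single-exon length {L} not divisible by 3")
        if cat == "exon_initial" and L % 3 != state.phase:
            raise ValueError(f"{name}: initial-exon length {L} inconsistent with phase {state.phase}")
        if cat == "exon_internal" and (c0 + L) % 3 != state.phase:
            raise ValueError(f"{name}: internal-exon length inconsistent with phases")
        if cat == "exon_terminal" and (c0 + L) % 3 != 0:
            raise ValueError(f"{name}: terminal exon must close the reading frame")
    else:
        cds = revcomp(seq)
        c0 = state.phase if state.phase is not None else 0
        if cat == "exon_single" and L % 3 != 0:
            raise ValueError(f"{name}: single-exon length {L} not divisible by 3")
        if cat == "exon_initial":
            if entry_phase is None:
                raise ValueError(f"{name}: entry_phase required")
            if L % 3 != entry_phase:
                raise ValueError(f"{name}: initial-exon length inconsistent with donor phase")
        if cat == "exon_terminal" and (c0 + L) % 3 != 0:
            raise ValueError(f"{name}: terminal exon must close the reading frame")
        if cat == "exon_internal":
            if entry_phase is None:
                raise ValueError(f"{name}: entry_phase required")
            if (state.phase + L) % 3 != entry_phase:
                raise ValueError(f"{name}: internal-exon length inconsistent with phases")

    if enforce_constraints:
        if _coding_constraint_violations(cds, cat):
            return NEG_INF
        # in-frame stop codons, except the closing codon of single/terminal
        up = cds.upper()
        limit = L - 3 if cat in ("exon_single", "exon_terminal") else L
        p = (3 - c0) % 3  # first position of a complete codon within the segment
        while p + 3 <= limit:
            if up[p : p + 3] in STOP_CODONS and "N" not in up[p : p + 3]:
                return NEG_INF
            p += 3

    coding = model.coding_model(cat, state.gc_tier)
    ldist = model.length_distribution(cat, state.gc_tier)
    lterm = ldist.logp(L)
    min_len = model.min_exon_len(cat)
    if L < min_len or L > cfg.max_exon_len:
        raise ValueError(f"{name}: exon length {L} outside [{min_len}, {cfg.max_exon_len}]")
    return lterm + coding.score(cds, c0, context=context)
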