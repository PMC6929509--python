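"""The generalized HMM container: configuration, transitions, emissions.

A :class:`GhmmModel` bundles the state set, the segment-level transition
matrix, the shared emission models (coding chains per exon category and GC
tier, one intron chain, one intergenic chain, donor/acceptor windows) and
the per-exon-state length distributions, together with the global
configuration.  Models serialize to a single JSON document whose write is
byte-stable (training twice on the same corpus yields identical files).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .emissions import (
    CodingMarkovModel,
    HomogeneousMarkovModel,
    LengthDistribution,
    SiteWindowModel,
    LOG_QUARTER,
)
from .states import EXON_CATEGORIES, StateSet, TIERS, build_state_set, build_topology

__all__ = ["ModelConfig", "TransitionMatrix", "GhmmModel", "uniform_model", "mirror_model"]

MIN_EXON_LEN = {
    "exon_single": 6,
    "exon_initial": 3,
    "exon_internal": 3,
    "exon_terminal": 3,
}

DONOR_CONSENSUS = {0: "G", 1: "T"}


def acceptor_consensus(width: int) -> dict[int, str]:
    return {width - 2: "A", width - 1: "G"}


@dataclass
class ModelConfig:
    """Global model parameters.

    ``k``: coding Markov order; ``low_t``/``high_t``: GC-tier cutoffs;
    ``d``: intron split length — short introns emit an explicit interior of
    at most ``d`` nt, longer introns emit a fixed ``d``-nt prefix followed
    by a geometric one-base-at-a-time tail; ``max_exon_len``: duration cap
    for explicit exon states; ``dss_window``/``ass_window``: donor and
    acceptor window widths (fully intronic, GT / AG consensus mandatory);
    ``pseudocount``: Laplace pseudocount added to transition counts;
    ``k_noncoding``: intron/intergenic Markov order; ``length_bandwidth``:
    triangular smoothing bandwidth (nt) for length histograms.
    """

    k: int = 4
    low_t: float = 0.40
    high_t: float = 0.60
    d: int = 40
    max_exon_len: int = 3000
    dss_window: int = 5
    ass_window: int = 23
    pseudocount: float = 1.0
    k_noncoding: int = 4
    length_bandwidth: int = 10

    def __post_init__(self) -> None:
        if not (0.0 <= self.low_t <= self.high_t <= 1.0):
            raise ValueError("require 0 <= lowT <= highT <= 1")
        if self.k < 0 or self.k_noncoding < 0:
            raise ValueError("Markov orders must be >= 0")
        if self.d < 1:
            raise ValueError("intron split length d must be >= 1")
        if self.max_exon_len < 3:
            raise ValueError("max_exon_len must be >= 3")
        if self.dss_window < 2 or self.ass_window < 2:
            raise ValueError("splice windows must cover the GT/AG consensus")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")

    @property
    def min_intron_len(self) -> int:
        return self.dss_window + 1 + self.ass_window


class TransitionMatrix:
    """Row-stochastic matrix over the state set, zero off the topology."""

    def __init__(self, state_set: StateSet, probs: np.ndarray):
        n = len(state_set)
        if probs.shape != (n, n):
            raise ValueError("transition matrix has wrong shape")
        self.state_set = state_set
        self.support = build_topology(state_set)
        off = probs.copy()
        for (a, b) in self.support:
            off[state_set.ordinal(a), state_set.ordinal(b)] = 0.0
        if np.abs(off).max() > 0:
            raise ValueError("nonzero probability outside the topology support")
        rows = probs.sum(axis=1)
        has_out = np.zeros(n, dtype=bool)
        for (a, _) in self.support:
            has_out[state_set.ordinal(a)] = True
        bad = has_out & (np.abs(rows - 1.0) > 1e-9)
        if bad.any():
            names = [state_set[int(i)].name for i in np.where(bad)[0]]
            raise ValueError(f"rows do not sum to 1: {names}")
        self.probs = probs
        with np.errstate(divide="ignore"):
            self.log_probs = np.log(probs)

    def p(self, a: str, b: str) -> float:
        return float(self.probs[self.state_set.ordinal(a), self.state_set.ordinal(b)])

    def logp(self, a: str, b: str) -> float:
        return float(self.log_probs[self.state_set.ordinal(a), self.state_set.ordinal(b)])


def _tiers(state_set: StateSet):
    return TIERS if state_set.tiered else (None,)


class GhmmModel:
    """Full generalized HMM: states, transitions, emissions, lengths."""

    def __init__(
        self,
        state_set: StateSet,
        transitions: TransitionMatrix,
        coding_models: dict,
        length_dists: dict,
        ir_model: HomogeneousMarkovModel,
        intron_model: HomogeneousMarkovModel,
        donor_model: SiteWindowModel,
        acceptor_model: SiteWindowModel,
        intron_length: LengthDistribution,
        config: ModelConfig,
    ):
        self.state_set = state_set
        self.transitions = transitions
        self._coding = coding_models  # (category, tier) -> CodingMarkovModel
        self._lengths = length_dists  # (category, tier) -> LengthDistribution
        self.ir_model = ir_model
        self.intron_model = intron_model
        self.donor_model = donor_model
        self.acceptor_model = acceptor_model
        self.intron_length = intron_length
        self.config = config
        if donor_model.width != config.dss_window or acceptor_model.width != config.ass_window:
            raise ValueError("site model widths disagree with the configuration")
        for cat in EXON_CATEGORIES:
            for t in _tiers(state_set):
                if (cat, t) not in coding_models or (cat, t) not in length_dists:
                    raise ValueError(f"missing emission or length model for ({cat}, {t})")

    # -- per-state lookups -------------------------------------------------
    def coding_model(self, category: str, tier: str | None) -> CodingMarkovModel:
        return self._coding[(category, tier)]

    def length_distribution(self, category: str, tier: str | None) -> LengthDistribution:
        return self._lengths[(category, tier)]

    def min_exon_len(self, category: str) -> int:
        return MIN_EXON_LEN[category]

    @property
    def emissions(self) -> dict:
        """Per-state emission model mapping (exon states share objects per
        category/tier; site, intron and intergenic states share theirs)."""
        out = {}
        for s in self.state_set:
            if s.is_exon:
                out[s.name] = self._coding[(s.category, s.gc_tier)]
            elif s.category == "donor_site":
                out[s.name] = self.donor_model
            elif s.category == "acceptor_site":
                out[s.name] = self.acceptor_model
            elif s.category == "intergenic":
                out[s.name] = self.ir_model
            else:
                out[s.name] = self.intron_model
        return out

    @property
    def lengths(self) -> dict:
        out = {}
        for s in self.state_set:
            if s.is_exon:
                out[s.name] = self._lengths[(s.category, s.gc_tier)]
            elif s.category == "intron_short":
                out[s.name] = self.intron_length
        return out

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        def key(cat, tier):
            return f"{cat}|{tier if tier is not None else '-'}"

        tm = {}
        for (a, b) in sorted(self.transitions.support):
            tm.setdefault(a, {})[b] = self.transitions.p(a, b)
        return {
            "format": "tiergene-model",
            "version": 1,
            "tiered": self.state_set.tiered,
            "config": asdict(self.config),
            "states": [s.name for s in self.state_set],
            "transitions": tm,
            "coding_models": {key(c, t): m.to_dict() for (c, t), m in sorted(self._coding.items(), key=lambda kv: key(*kv[0]))},
            "length_dists": {key(c, t): m.to_dict() for (c, t), m in sorted(self._lengths.items(), key=lambda kv: key(*kv[0]))},
            "ir_model": self.ir_model.to_dict(),
            "intron_model": self.intron_model.to_dict(),
            "donor_model": self.donor_model.to_dict(),
            "acceptor_model": self.acceptor_model.to_dict(),
            "intron_length": self.intron_length.to_dict(),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":")) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "GhmmModel":
        if d.get("format") != "tiergene-model":
            raise ValueError("not a model file")
        config = ModelConfig(**d["config"])
        state_set = build_state_set(tiered=d["tiered"])
        if d["states"] != [s.name for s in state_set]:
            raise ValueError("model file state list does not match the canonical ordering")
        n = len(state_set)
        probs = np.zeros((n, n))
        for a, row in d["transitions"].items():
            for b, p in row.items():
                probs[state_set.ordinal(a), state_set.ordinal(b)] = p
        transitions = TransitionMatrix(state_set, probs)

        def unkey(s: str):
            cat, tier = s.split("|")
            return cat, (None if tier == "-" else tier)

        coding = {unkey(k): CodingMarkovModel.from_dict(v) for k, v in d["coding_models"].items()}
        lengths = {unkey(k): LengthDistribution.from_dict(v) for k, v in d["length_dists"].items()}
        return cls(
            state_set,
            transitions,
            coding,
            lengths,
            HomogeneousMarkovModel.from_dict(d["ir_model"]),
            HomogeneousMarkovModel.from_dict(d["intron_model"]),
            SiteWindowModel.from_dict(d["donor_model"]),
            SiteWindowModel.from_dict(d["acceptor_model"]),
            LengthDistribution.from_dict(d["intron_length"]),
            config,
        )

    @classmethod
    def load(cls, path: str | Path) -> "GhmmModel":
        try:
            d = json.loads(Path(path).read_text())
        except json.JSONDecodeError as e:
            raise ValueError(f"corrupt model file {path}: {e}") from e
        return cls.from_dict(d)


# -- default (untrained) model ------------------------------------------------

IR_SELF_LOOP = 0.998  # default expected intergenic stretch ~500 nt
I_GEO_SELF_LOOP = 0.98  # default geometric intron tail, mean ~50 nt


def uniform_transitions(state_set: StateSet, ir_self: float = IR_SELF_LOOP,
                        geo_self: float = I_GEO_SELF_LOOP) -> TransitionMatrix:
    """Documented defaults: uniform over legal edges, except the single-base
    self-loops (intergenic stay probability, geometric intron tail)."""
    support = build_topology(state_set)
    n = len(state_set)
    probs = np.zeros((n, n))
    out_edges: dict[str, list[str]] = {}
    for (a, b) in support:
        out_edges.setdefault(a, []).append(b)
    for a, outs in out_edges.items():
        ia = state_set.ordinal(a)
        cat = state_set[a].category
        if cat == "intergenic":
            others = [b for b in outs if b != a]
            probs[ia, ia] = ir_self
            for b in others:
                probs[ia, state_set.ordinal(b)] = (1.0 - ir_self) / len(others)
        elif cat == "intron_geometric":
            exit_, = [b for b in outs if b != a]
            probs[ia, ia] = geo_self
            probs[ia, state_set.ordinal(exit_)] = 1.0 - geo_self
        else:
            for b in outs:
                probs[ia, state_set.ordinal(b)] = 1.0 / len(outs)
    return TransitionMatrix(state_set, probs)


def uniform_model(config: ModelConfig | None = None, tiered: bool = True) -> GhmmModel:
    """An untrained model with uniform emissions — mainly for tests and as
    the starting point for training."""
    cfg = config or ModelConfig()
    state_set = build_state_set(tiered=tiered)
    coding = {}
    lengths = {}
    for cat in EXON_CATEGORIES:
        for t in _tiers(state_set):
            coding[(cat, t)] = CodingMarkovModel(
                cfg.k, [np.full((3, 4 ** o, 4), LOG_QUARTER) for o in range(cfg.k + 1)]
            )
            lo = MIN_EXON_LEN[cat]
            pmf = np.zeros(cfg.max_exon_len)
            pmf[lo - 1 :] = 1.0 / (cfg.max_exon_len - lo + 1)
            with np.errstate(divide="ignore"):
                lengths[(cat, t)] = LengthDistribution(np.log(pmf))
    homo = lambda k: HomogeneousMarkovModel(k, [np.full((4 ** o, 4), LOG_QUARTER) for o in range(k + 1)])
    donor = SiteWindowModel(
        cfg.dss_window,
        _consensus_lp(cfg.dss_window, DONOR_CONSENSUS),
        DONOR_CONSENSUS,
    )
    acc_cons = acceptor_consensus(cfg.ass_window)
    acceptor = SiteWindowModel(cfg.ass_window, _consensus_lp(cfg.ass_window, acc_cons), acc_cons)
    with np.errstate(divide="ignore"):
        ilen = LengthDistribution(np.log(np.full(cfg.d, 1.0 / cfg.d)))
    return GhmmModel(
        state_set,
        uniform_transitions(state_set),
        coding,
        lengths,
        homo(cfg.k_noncoding),
        homo(cfg.k_noncoding),
        donor,
        acceptor,
        ilen,
        cfg,
    )


def _consensus_lp(width: int, consensus: dict[int, str]) -> np.ndarray:
    from .emissions import encode, NEG_INF

    lp = np.full((width, 4), LOG_QUARTER)
    for pos, base in consensus.items():
        lp[pos, :] = NEG_INF
        lp[pos, encode(base)[0]] = 0.0
    return lp


# -- exact strand mirror -------------------------------------------------------


def _mirror_edge_value_map(state_set: StateSet) -> dict[tuple[str, str], tuple[str, str]]:
    """The phase-negating path correspondence: for each support edge of the
    mirrored model, the original support edge whose probability it inherits
    (before the gauge correction).  Probability-one structural edges map to
    structural edges."""
    ts = _tiers(state_set)

    def name(base, t):
        suff = {"high": "_H", "medium": "_M", "low": "_L", None: ""}[t]
        return base + suff

    m: dict[tuple[str, str], tuple[str, str]] = {("IR", "IR"): ("IR", "IR")}

    def pair(e1, e2):
        m[e1] = e2
        m[e2] = e1

    for t in ts:
        pair(("IR", name("E_single", t)), ("IR", name("rE_single", t)))
        pair((name("E_single", t), "IR"), (name("rE_single", t), "IR"))
        pair((name("E_term", t), "IR"), (name("rE_init", t), "IR"))
    for x in range(3):
        for t in ts:
            pair(("IR", name(f"rE_term_{x}", t)), (f"ASS_{x}", name("E_term", t)))
            pair((f"rDSS_{x}", name("rE_init", t)), ("IR", name(f"E_init_{x}", t)))
            pair((name(f"E_init_{x}", t), f"DSS_{x}"), (name(f"rE_term_{x}", t), f"rASS_{x}"))
            pair((name(f"E_int_{x}", t), f"DSS_{x}"), (name(f"rE_int_{x}", t), f"rASS_{x}"))
            for y in range(3):
                pair((f"rDSS_{x}", name(f"rE_int_{y}", t)), (f"ASS_{y}", name(f"E_int_{x}", t)))
        for kind in ("I_short", "I_fixed"):
            pair((f"DSS_{x}", f"{kind}_{x}"), (f"rASS_{x}", f"r{kind}_{x}"))
        pair((f"I_short_{x}", f"ASS_{x}"), (f"rI_short_{x}", f"rDSS_{x}"))
        pair((f"I_fixed_{x}", f"I_geo_{x}"), (f"rI_fixed_{x}", f"rI_geo_{x}"))
        pair((f"I_geo_{x}", f"I_geo_{x}"), (f"rI_geo_{x}", f"rI_geo_{x}"))
        pair((f"I_geo_{x}", f"ASS_{x}"), (f"rI_geo_{x}", f"rDSS_{x}"))
    return m


def mirror_model(model: GhmmModel) -> GhmmModel:
    """The strand-mirrored model: decoding revcomp(seq) under it yields the
    coordinate-mirrored parse of decoding seq under ``model``, with exactly
    equal joint log-probability.

    Transition probabilities are reassigned through the phase-negating path
    correspondence and then gauge-corrected by the Perron eigenvector of the
    raw reassigned matrix (eigenvalue 1), which restores row-stochasticity
    while leaving every intergenic-to-intergenic path product unchanged.
    The intergenic emission chain is replaced by its reverse-complement
    (right-context) form; all stranded emission models are shared.
    """
    ss = model.state_set
    n = len(ss)
    emap = _mirror_edge_value_map(ss)
    support = model.transitions.support
    if set(emap) != support:
        missing = support ^ set(emap)
        raise AssertionError(f"mirror edge map does not cover the support: {sorted(missing)[:4]}")
    raw = np.zeros((n, n))
    for (u, v), (a, b) in emap.items():
        raw[ss.ordinal(u), ss.ordinal(v)] = model.transitions.probs[ss.ordinal(a), ss.ordinal(b)]
    # gauge correction: Perron eigenvector of raw, eigenvalue 1
    w, vecs = np.linalg.eig(raw)
    i = int(np.argmin(np.abs(w - 1.0)))
    if abs(w[i] - 1.0) > 1e-8:
        raise AssertionError(f"raw mirror matrix has no unit eigenvalue (closest {w[i]})")
    phi = np.real(vecs[:, i])
    phi = phi * np.sign(phi[np.argmax(np.abs(phi))])
    if (phi <= 0).any():
        raise AssertionError("Perron eigenvector not strictly positive")
    probs = raw * phi[None, :] / phi[:, None]
    probs[raw == 0.0] = 0.0
    # clean tiny numerical drift on the rows
    rows = probs.sum(axis=1)
    nz = rows > 0
    probs[nz] /= rows[nz, None]
    mirrored_transitions = TransitionMatrix(ss, probs)
    return GhmmModel(
        ss,
        mirrored_transitions,
        model._coding,
        model._lengths,
        model.ir_model.rc_mirror(),
        model.intron_model,
        model.donor_model,
        model.acceptor_model,
        model.intron_length,
        model.config,
    )
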