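"""State space and transition topology of the GC-tiered gene-model GHMM.

The model labels genomic sequence with a generalized hidden Markov model
whose exon states are tripled by GC tier (high / medium / low), so that a
gene whose exons drift from GC-rich to GC-poor along the transcript can be
decoded as a path through different tier states.  The canonical state set
has 79 states: an intergenic state, tiered exon states for single, initial,
internal and terminal exons on both strands, donor/acceptor splice-site
states, and a three-part intron length device (explicit short intron, fixed
prefix window, geometric tail) — all phased over the three reading frames.

Phase convention
----------------
The exponent carried by a phased exon state is the position of the exon's
last base within its codon, i.e. the cumulative coding length mod 3 at the
end of the exon (forward strand).  Non-exon gene states carry the phase of
the preceding exon.  On the reverse strand — decoded left-to-right in
genomic coordinates, which is 3'-to-5' along the transcript — an exon state
carries the transcript phase at which the exon is *entered* in transcript
order, so reverse terminal exons are phased while reverse initial and
single exons are not (the transcript always starts at phase 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "CATEGORIES",
    "EXON_CATEGORIES",
    "TIERS",
    "State",
    "StateSet",
    "build_state_set",
    "build_topology",
    "collapse_tiers",
    "collapse_map",
    "mirror_state_map",
]

TIERS = ("high", "medium", "low")
_TIER_SUFFIX = {"high": "H", "medium": "M", "low": "L"}

EXON_CATEGORIES = ("exon_single", "exon_initial", "exon_internal", "exon_terminal")
CATEGORIES = EXON_CATEGORIES + (
    "intergenic",
    "donor_site",
    "acceptor_site",
    "intron_short",
    "intron_fixed",
    "intron_geometric",
)

_DURATION_CLASS = {
    "exon_single": "explicit",
    "exon_initial": "explicit",
    "exon_internal": "explicit",
    "exon_terminal": "explicit",
    "intron_short": "explicit",
    "donor_site": "fixed_window",
    "acceptor_site": "fixed_window",
    "intron_fixed": "fixed_window",
    "intron_geometric": "geometric",
    "intergenic": "single_base",
}


@dataclass(frozen=True)
class State:
    """One HMM state.

    ``phase`` is ``None`` for unphased states, ``gc_tier`` is ``None`` for
    non-exon states and for exon states of a tier-collapsed (baseline)
    state set.
    """

    name: str
    category: str
    strand: str  # "forward" | "reverse"
    phase: int | None
    gc_tier: str | None

    @property
    def duration_class(self) -> str:
        return _DURATION_CLASS[self.category]

    @property
    def is_exon(self) -> bool:
        return self.category in EXON_CATEGORIES

    def __repr__(self) -> str:  # compact, name is unambiguous
        return f"State({self.name})"


class StateSet:
    """Ordered, indexed collection of states with stable ordering."""

    def __init__(self, states: list[State], tiered: bool):
        names = [s.name for s in states]
        if len(set(names)) != len(names):
            raise ValueError("duplicate state names")
        self.states: tuple[State, ...] = tuple(states)
        self.tiered = tiered
        self.index: dict[str, int] = {s.name: i for i, s in enumerate(states)}

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self) -> Iterator[State]:
        return iter(self.states)

    def __getitem__(self, key: int | str) -> State:
        if isinstance(key, str):
            return self.states[self.index[key]]
        return self.states[key]

    def __contains__(self, name: str) -> bool:
        return name in self.index

    def ordinal(self, name: str) -> int:
        return self.index[name]

    def exon_states(self) -> list[State]:
        return [s for s in self.states if s.is_exon]


def _tiers_for(tiered: bool) -> tuple[str | None, ...]:
    return TIERS if tiered else (None,)


def _tname(base: str, tier: str | None) -> str:
    return f"{base}_{_TIER_SUFFIX[tier]}" if tier is not None else base


def build_state_set(tiered: bool = True) -> StateSet:
    """Enumerate the canonical state set in deterministic order.

    With ``tiered=True`` (default) this is the 79-state set; with
    ``tiered=False`` each high/medium/low triple is a single state, giving
    the 47-state single-tier baseline.
    """
    ts = _tiers_for(tiered)
    states: list[State] = [State("IR", "intergenic", "forward", None, None)]
    for t in ts:
        states.append(State(_tname("E_single", t), "exon_single", "forward", None, t))
    for t in ts:
        states.append(State(_tname("E_term", t), "exon_terminal", "forward", None, t))
    for t in ts:
        states.append(State(_tname("rE_single", t), "exon_single", "reverse", None, t))
    for t in ts:
        states.append(State(_tname("rE_init", t), "exon_initial", "reverse", None, t))
    for i in range(3):
        for t in ts:
            states.append(State(_tname(f"E_init_{i}", t), "exon_initial", "forward", i, t))
        states.append(State(f"DSS_{i}", "donor_site", "forward", i, None))
        states.append(State(f"I_short_{i}", "intron_short", "forward", i, None))
        states.append(State(f"I_fixed_{i}", "intron_fixed", "forward", i, None))
        states.append(State(f"I_geo_{i}", "intron_geometric", "forward", i, None))
    for i in range(3):
        states.append(State(f"ASS_{i}", "acceptor_site", "forward", i, None))
        for t in ts:
            states.append(State(_tname(f"E_int_{i}", t), "exon_internal", "forward", i, t))
    for i in range(3):
        for t in ts:
            states.append(State(_tname(f"rE_term_{i}", t), "exon_terminal", "reverse", i, t))
        states.append(State(f"rDSS_{i}", "donor_site", "reverse", i, None))
    for i in range(3):
        states.append(State(f"rI_short_{i}", "intron_short", "reverse", i, None))
        states.append(State(f"rI_fixed_{i}", "intron_fixed", "reverse", i, None))
        states.append(State(f"rI_geo_{i}", "intron_geometric", "reverse", i, None))
        states.append(State(f"rASS_{i}", "acceptor_site", "reverse", i, None))
        for t in ts:
            states.append(State(_tname(f"rE_int_{i}", t), "exon_internal", "reverse", i, t))
    return StateSet(states, tiered)


def collapse_tiers(state_set: StateSet) -> StateSet:
    """Merge each high/medium/low exon triple into a single state.

    Idempotent: collapsing an already collapsed set returns an equal set.
    """
    return build_state_set(tiered=False)


def collapse_map(state_set: StateSet) -> dict[str, str]:
    """Map each state name of ``state_set`` to its tier-collapsed name."""
    out = {}
    for s in state_set:
        if s.gc_tier is not None:
            base = s.name.rsplit("_", 1)[0]
            out[s.name] = base
        else:
            out[s.name] = s.name
    return out


def _exon_tiers(state_set: StateSet) -> tuple[str | None, ...]:
    return TIERS if state_set.tiered else (None,)


def build_topology(state_set: StateSet) -> set[tuple[str, str]]:
    """The set of legal directed transitions (support of the matrix).

    Gene syntax on the forward strand reads, left to right: intergenic,
    initial (or single) exon, donor site, intron (short, or fixed prefix
    plus geometric tail), acceptor site, internal exons with further
    introns, terminal exon, intergenic.  Reverse-strand genes are traversed
    genomically left to right as terminal exon first, so the reverse chain
    runs IR, reverse terminal exon, reverse acceptor, intron, reverse
    donor, reverse internal/initial exon, IR.  Every tier triple receives
    parallel edges.
    """
    expected = build_state_set(tiered=state_set.tiered)
    if [s.name for s in state_set] != [s.name for s in expected]:
        raise ValueError("state_set is not a canonical state set")
    ts = _exon_tiers(state_set)
    edges: set[tuple[str, str]] = {("IR", "IR")}

    def add(a: str, b: str) -> None:
        edges.add((a, b))

    for t in ts:
        add("IR", _tname("E_single", t))
        add(_tname("E_single", t), "IR")
        add("IR", _tname("rE_single", t))
        add(_tname("rE_single", t), "IR")
        add(_tname("E_term", t), "IR")
        add(_tname("rE_init", t), "IR")
    for i in range(3):
        for t in ts:
            add("IR", _tname(f"E_init_{i}", t))
            add(_tname(f"E_init_{i}", t), f"DSS_{i}")
            add(_tname(f"E_int_{i}", t), f"DSS_{i}")
            add("IR", _tname(f"rE_term_{i}", t))
            add(_tname(f"rE_term_{i}", t), f"rASS_{i}")
            add(_tname(f"rE_int_{i}", t), f"rASS_{i}")
        add(f"DSS_{i}", f"I_short_{i}")
        add(f"DSS_{i}", f"I_fixed_{i}")
        add(f"I_short_{i}", f"ASS_{i}")
        add(f"I_fixed_{i}", f"I_geo_{i}")
        add(f"I_geo_{i}", f"I_geo_{i}")
        add(f"I_geo_{i}", f"ASS_{i}")
        add(f"rASS_{i}", f"rI_short_{i}")
        add(f"rASS_{i}", f"rI_fixed_{i}")
        add(f"rI_short_{i}", f"rDSS_{i}")
        add(f"rI_fixed_{i}", f"rI_geo_{i}")
        add(f"rI_geo_{i}", f"rI_geo_{i}")
        add(f"rI_geo_{i}", f"rDSS_{i}")
        for j in range(3):
            for t in ts:
                add(f"ASS_{i}", _tname(f"E_int_{j}", t))
                add(f"rDSS_{i}", _tname(f"rE_int_{j}", t))
        for t in ts:
            add(f"ASS_{i}", _tname("E_term", t))
            add(f"rDSS_{i}", _tname("rE_init", t))
    return edges


def mirror_state_map(state_set: StateSet) -> dict[str, str]:
    """Structural strand mirror: the involution pairing each forward state
    with the reverse state playing the same role in the genomic left-to-
    right walk (initial exon <-> reverse terminal exon, donor <-> reverse
    acceptor, ...).  Maps the topology onto itself edge-for-edge.
    """
    ts = _exon_tiers(state_set)
    m: dict[str, str] = {"IR": "IR"}

    def pair(a: str, b: str) -> None:
        m[a] = b
        m[b] = a

    for t in ts:
        pair(_tname("E_single", t), _tname("rE_single", t))
        pair(_tname("E_term", t), _tname("rE_init", t))
    for i in range(3):
        for t in ts:
            pair(_tname(f"E_init_{i}", t), _tname(f"rE_term_{i}", t))
            pair(_tname(f"E_int_{i}", t), _tname(f"rE_int_{i}", t))
        pair(f"DSS_{i}", f"rASS_{i}")
        pair(f"ASS_{i}", f"rDSS_{i}")
        pair(f"I_short_{i}", f"rI_short_{i}")
        pair(f"I_fixed_{i}", f"rI_fixed_{i}")
        pair(f"I_geo_{i}", f"rI_geo_{i}")
    return m
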