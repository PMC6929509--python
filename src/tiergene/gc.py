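"""GC content computation and exon tier classification.

Exons are assigned to one of three GC tiers by two cutoffs ``lowT`` and
``highT``: strictly below ``lowT`` is *low*, strictly above ``highT`` is
*high*, everything else (boundaries included) is *medium*.
"""

from __future__ import annotations

from .genes import GeneStructure

__all__ = ["gc_content", "classify_exon", "classify_gc", "gene_gc_profile"]

_GC = frozenset("GCgc")
_VALID = frozenset("ACGTNacgtn")


def gc_content(seq: str) -> float:
    """Fraction (G + C) / (non-N bases), case-insensitive.

    N bases are excluded from both numerator and denominator.  Raises
    ``ValueError`` on an empty sequence or one consisting only of N.
    """
    if not seq:
        raise ValueError("cannot compute GC content of an empty sequence")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"invalid bases in sequence: {sorted(bad)}")
    denom = len(seq) - seq.count("N") - seq.count("n")
    if denom == 0:
        raise ValueError("GC content undefined: sequence is all N")
    gc = sum(1 for c in seq if c in _GC)
    return gc / denom


def classify_gc(gc: float, low_t: float, high_t: float) -> str:
    """Tier for a GC fraction. Boundary values are medium (strict cutoffs)."""
    if low_t > high_t:
        raise ValueError(f"lowT ({low_t}) must not exceed highT ({high_t})")
    if gc < low_t:
        return "low"
    if gc > high_t:
        return "high"
    return "medium"


def classify_exon(seq: str, low_t: float, high_t: float) -> str:
    return classify_gc(gc_content(seq), low_t, high_t)


def gene_gc_profile(gene: GeneStructure, genome: dict[str, str] | str) -> list[float]:
    """Per-exon GC fractions ordered 5'-to-3' along the coding strand.

    ``genome`` is either the sequence of the gene's region or a mapping of
    sequence id to sequence.  GC is complement-invariant, so exon sequences
    are read from the forward strand; only the ordering is strand-aware.
    """
    seq = genome[gene.seqid] if isinstance(genome, dict) else genome
    vals = []
    for start, end in gene.exons:
        if start < 0 or end > len(seq) or start >= end:
            raise ValueError(f"exon ({start}, {end}) out of bounds for sequence of length {len(seq)}")
        vals.append(gc_content(seq[start:end]))
    if gene.strand == "reverse":
        vals.reverse()
    return vals
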