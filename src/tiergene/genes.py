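"""Gene structures and structural validation.

A :class:`GeneStructure` records a protein-coding gene as ordered exon
intervals (0-based, half-open, genomic coordinates) on one strand of one
sequence.  It is used both for training/evaluation truth and for decoder
predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "STOP_CODONS",
    "GeneStructure",
    "revcomp",
    "validate_gene",
]

STOP_CODONS = ("TAA", "TAG", "TGA")

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class GeneStructure:
    """A gene: strand, ordered exon intervals and optional state labels.

    ``exons`` are coding (CDS) intervals sorted by genomic coordinate.
    ``exon_labels`` — one ``(category, phase, tier)`` triple per exon in the
    same genomic order — is filled in by training labelling or by the
    decoder; ``phase``/``tier`` may be ``None``.
    """

    gene_id: str
    seqid: str
    strand: str  # "forward" | "reverse"
    exons: list[tuple[int, int]]
    exon_labels: list[tuple[str, int | None, str | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("forward", "reverse"):
            raise ValueError(f"bad strand {self.strand!r}")
        for (s, e) in self.exons:
            if s >= e:
                raise ValueError(f"empty exon interval ({s}, {e})")
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 <= e0:
                raise ValueError("exons out of order or overlapping")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def coding_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def exons_in_transcript_order(self) -> list[tuple[int, int]]:
        return list(self.exons) if self.strand == "forward" else list(reversed(self.exons))

    def cds(self, seq: str) -> str:
        """Spliced coding sequence, 5'-to-3' in transcript orientation."""
        parts = [seq[s:e] for s, e in self.exons]
        joined = "".join(parts)
        return joined if self.strand == "forward" else revcomp(joined)

    def exon_key(self) -> frozenset[tuple[int, int, str]]:
        return frozenset((s, e, self.strand) for s, e in self.exons)


def validate_gene(
    gene: GeneStructure,
    seq: str,
    min_intron: int = 4,
) -> list[str]:
    """Check biological well-formedness; return a list of problems (empty
    when valid).

    Checks: ATG start, stop-codon end, coding length divisible by three, no
    in-frame stop codon before the final one, GT..AG intron boundaries and
    a minimum intron length.
    """
    problems: list[str] = []
    start, end = gene.span
    if start < 0 or end > len(seq):
        return [f"gene {gene.gene_id}: coordinates outside sequence"]
    cds = gene.cds(seq).upper()
    if len(cds) % 3 != 0:
        problems.append(f"coding length {len(cds)} not divisible by 3")
    if not cds.startswith("ATG"):
        problems.append("does not start with ATG")
    if len(cds) % 3 == 0:
        if cds[-3:] not in STOP_CODONS:
            problems.append(f"does not end with a stop codon ({cds[-3:]})")
        internal = [cds[i : i + 3] for i in range(0, len(cds) - 3, 3)]
        n_stop = sum(1 for c in internal if c in STOP_CODONS)
        if n_stop:
            problems.append(f"{n_stop} in-frame stop codon(s) before the final codon")
    if len(cds) < 6:
        problems.append("coding sequence shorter than start plus stop codon")
    tx = gene.exons_in_transcript_order()
    for (a, b) in zip(tx, tx[1:]):
        if gene.strand == "forward":
            ia, ib = a[1], b[0]  # intron interval [ia, ib)
            donor, acceptor = seq[ia : ia + 2].upper(), seq[ib - 2 : ib].upper()
        else:
            ia, ib = b[1], a[0]
            donor = revcomp(seq[ib - 2 : ib]).upper()
            acceptor = revcomp(seq[ia : ia + 2]).upper()
        if ib - ia < min_intron:
            problems.append(f"intron [{ia}, {ib}) shorter than {min_intron}")
        if donor != "GT":
            problems.append(f"intron [{ia}, {ib}) donor is {donor}, not GT")
        if acceptor != "AG":
            problems.append(f"intron [{ia}, {ib}) acceptor is {acceptor}, not AG")
    return problems
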