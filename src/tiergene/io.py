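"""FASTA and GFF3 reading/writing and coordinate conversion.

Internal coordinates are 0-based half-open; GFF3 is 1-based inclusive.  The
conversion happens only here.  CDS rows carry the standard GFF3 phase
column (bases to skip to reach the next codon start) and, when the gene has
tier labels, a ``gc_tier`` attribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .genes import GeneStructure

__all__ = ["SequenceRecord", "read_fasta", "write_fasta", "read_gff3", "write_gff3"]

_ALLOWED = set("ACGTN")


@dataclass
class SequenceRecord:
    id: str
    sequence: str


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA; fold to uppercase, map non-ACGTN characters to N."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence {rec.id!r} in {path}")
        if set(seq) - _ALLOWED:
            warnings.warn(f"{rec.id}: non-ACGTN characters mapped to N")
            seq = "".join(c if c in _ALLOWED else "N" for c in seq)
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _attr_dict(attr_field: str) -> dict[str, str]:
    out = {}
    for item in attr_field.strip().split(";"):
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> list[GeneStructure]:
    """Parse gene structures from GFF3 CDS rows grouped by Parent (or ID).

    Uses an in-memory gffutils database so hierarchy quirks (gene/mRNA/CDS
    or bare CDS rows) are handled uniformly.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    groups: dict[str, list] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent") or cds.attributes.get("ID") or ["cds"]
        groups.setdefault(parents[0], []).append(cds)
    genes: list[GeneStructure] = []
    for key in sorted(groups):
        rows = sorted(groups[key], key=lambda c: c.start)
        seqids = {c.seqid for c in rows}
        strands = {c.strand for c in rows}
        if len(seqids) != 1 or len(strands) != 1:
            raise ValueError(f"gene {key}: CDS rows span sequences or strands")
        strand = {"+": "forward", "-": "reverse"}.get(rows[0].strand)
        if strand is None:
            raise ValueError(f"gene {key}: missing strand")
        exons = [(c.start - 1, c.end) for c in rows]  # 1-based inclusive -> half-open
        labels = []
        for c in rows:
            tier = c.attributes.get("gc_tier", [None])[0]
            labels.append(("exon", None, tier) if tier else ("exon", None, None))
        gene_id = key
        # prefer the grandparent gene id when present
        try:
            parent = next(db.parents(rows[0], featuretype="gene"), None)
            if parent is not None:
                gene_id = parent.id
        except Exception:
            pass
        genes.append(GeneStructure(gene_id, rows[0].seqid, strand, exons))
    return genes


def write_gff3(genes: list[GeneStructure], path: str | Path, source: str = "tiergene") -> None:
    """Emit gene/mRNA/CDS rows; the CDS phase column is derived from the
    cumulative coding length in transcript order."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in sorted(genes, key=lambda g: (g.seqid, g.span[0], g.gene_id)):
            strand = "+" if gene.strand == "forward" else "-"
            gstart, gend = gene.span
            gid, mid = gene.gene_id, gene.gene_id + ".m1"
            fh.write(
                f"{gene.seqid}\t{source}\tgene\t{gstart + 1}\t{gend}\t.\t{strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{gene.seqid}\t{source}\tmRNA\t{gstart + 1}\t{gend}\t.\t{strand}\t.\t"
                f"ID={mid};Parent={gid}\n"
            )
            tx = gene.exons_in_transcript_order()
            cum = 0
            phases = {}
            for (s, e) in tx:
                phases[(s, e)] = (3 - (cum % 3)) % 3
                cum += e - s
            labels = {tuple(ex): lab for ex, lab in zip(gene.exons, gene.exon_labels)}
            for idx, (s, e) in enumerate(gene.exons):
                attrs = f"ID={mid}.cds{idx + 1};Parent={mid}"
                lab = labels.get((s, e))
                if lab and lab[2]:
                    attrs += f";gc_tier={lab[2]}"
                fh.write(
                    f"{gene.seqid}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{strand}\t"
                    f"{phases[(s, e)]}\t{attrs}\n"
                )
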