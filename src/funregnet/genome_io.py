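"""Genome and annotation I/O plus strand-aware promoter extraction.

Coordinate conventions
----------------------
GFF3 genes are stored 1-based inclusive, exactly as in the file.  Promoter
intervals are 0-based half-open genomic intervals.  A promoter is the fixed
window immediately upstream of the annotated gene start (upstream in the
gene's own orientation), oriented 5'->3' relative to the gene, so for a
minus-strand gene the stored sequence is the reverse complement of the
genomic slice downstream of ``end``.

Promoters running off a contig edge are truncated (never padded) and
flagged.  Overlap with neighbouring genes is not trimmed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeSequence",
    "GeneRecord",
    "PromoterRecord",
    "read_genome",
    "read_genes",
    "extract_promoter",
    "write_promoters",
    "read_promoters",
]


@dataclass(frozen=True)
class GenomeSequence:
    """A single contig: id plus upper-cased DNA over {A,C,G,T,N}."""

    contig_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneRecord:
    """A gene feature with 1-based inclusive GFF3 coordinates."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # "+" or "-"

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid coordinates "
                f"start={self.start} end={self.end} (need 1 <= start <= end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class PromoterRecord:
    """An extracted promoter.

    ``interval`` is the 0-based half-open genomic interval of the slice;
    ``sequence`` is oriented 5'->3' relative to the gene (reverse
    complemented for minus-strand genes); ``truncated`` is set when the
    window was clipped at a contig boundary.
    """

    gene_id: str
    contig_id: str
    interval: tuple[int, int]
    strand: str
    sequence: str
    truncated: bool


def read_genome(fasta_path) -> dict[str, GenomeSequence]:
    """Read a FASTA file into a mapping of contig id -> GenomeSequence.

    Contig ids are the first whitespace-delimited token of each header.
    Duplicate ids and empty files are hard errors.  Sequences are
    upper-cased; ambiguity codes such as N are kept verbatim.
    """
    genome: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate contig id {rec.id!r} in {fasta_path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"contig {rec.id!r} in {fasta_path} has empty sequence")
        genome[rec.id] = GenomeSequence(rec.id, seq)
    if not genome:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    return genome


def read_genes(gff3_path) -> list[GeneRecord]:
    """Read gene-level features from a GFF3 file.

    Returns one :class:`GeneRecord` per feature of type ``gene``, keeping
    coordinates 1-based inclusive.  The gene id is taken from the ``ID``
    attribute (falling back to ``locus_tag``).  A gene without either is a
    hard error naming the offending line.  Features of other types (mRNA,
    CDS, exon, ...) are ignored; a file with no gene features yields an
    empty list with a warning.
    """
    records: list[GeneRecord] = []
    seen: set[str] = set()
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            feature = feature_from_line(line)
            if feature.featuretype != "gene":
                continue
            attrs = feature.attributes
            if "ID" in attrs and attrs["ID"]:
                gene_id = attrs["ID"][0]
            elif "locus_tag" in attrs and attrs["locus_tag"]:
                gene_id = attrs["locus_tag"][0]
            else:
                raise ValueError(
                    f"{gff3_path}:{lineno}: gene feature lacks an ID/locus_tag "
                    f"attribute: {stripped!r}"
                )
            if feature.start > feature.end:
                raise ValueError(
                    f"{gff3_path}:{lineno}: gene {gene_id} has start > end "
                    f"({feature.start} > {feature.end})"
                )
            if gene_id in seen:
                raise ValueError(f"{gff3_path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            strand = feature.strand
            if strand not in ("+", "-"):
                warnings.warn(
                    f"gene {gene_id} has strand {strand!r}; treating as '+'", stacklevel=2
                )
                strand = "+"
            records.append(
                GeneRecord(gene_id, feature.seqid, int(feature.start), int(feature.end), strand)
            )
    if not records:
        warnings.warn(f"no gene features found in {gff3_path}", stacklevel=2)
    return records


def extract_promoter(
    gene: GeneRecord, genome: dict[str, GenomeSequence], length: int = 1000
) -> PromoterRecord:
    """Extract the promoter window of ``length`` bp upstream of ``gene``.

    Plus strand: genomic slice ``[start-1-length, start-1)`` (0-based
    half-open), clipped at 0.  Minus strand: slice ``[end, end+length)``
    clipped at the contig end, then reverse complemented so the returned
    sequence reads 5'->3' relative to the gene.
    """
    if length < 1:
        raise ValueError(f"promoter length must be positive, got {length}")
    contig = genome.get(gene.contig_id)
    if contig is None:
        raise KeyError(
            f"gene {gene.gene_id}: contig {gene.contig_id!r} not present in genome"
        )
    clen = len(contig)
    if gene.end > clen:
        raise ValueError(
            f"gene {gene.gene_id} ends at {gene.end} beyond contig "
            f"{gene.contig_id} length {clen}"
        )
    if gene.strand == "+":
        hi = gene.start - 1  # 0-based position of the gene start
        lo = max(0, hi - length)
        seq = contig.sequence[lo:hi]
    else:
        lo = gene.end  # 0-based position just past the gene end
        hi = min(clen, lo + length)
        seq = str(Seq(contig.sequence[lo:hi]).reverse_complement())
    return PromoterRecord(
        gene_id=gene.gene_id,
        contig_id=gene.contig_id,
        interval=(lo, hi),
        strand=gene.strand,
        sequence=seq,
        truncated=len(seq) < length,
    )


def write_promoters(records: list[PromoterRecord], fasta_path) -> None:
    """Write promoters as FASTA with headers ``gene_id contig:lo-hi(strand)``.

    Round-trips through :func:`read_promoters`.  Zero-length promoters
    (genes at a contig edge) are emitted with an empty body and a warning.
    """
    if not records:
        raise ValueError("no promoter records to write")
    with open(fasta_path, "w") as fh:
        for rec in records:
            if not rec.sequence:
                warnings.warn(
                    f"promoter of {rec.gene_id} is empty (gene at contig edge)",
                    stacklevel=2,
                )
            lo, hi = rec.interval
            fh.write(f">{rec.gene_id} {rec.contig_id}:{lo}-{hi}({rec.strand})\n")
            for i in range(0, len(rec.sequence), 80):
                fh.write(rec.sequence[i : i + 80] + "\n")


def read_promoters(fasta_path) -> list[PromoterRecord]:
    """Read back a promoter FASTA written by :func:`write_promoters`."""
    records: list[PromoterRecord] = []
    current_header: str | None = None
    chunks: list[str] = []

    def flush():
        if current_header is None:
            return
        parts = current_header.split()
        gene_id = parts[0]
        loc = parts[1]
        contig_id, rest = loc.rsplit(":", 1)
        span, strand = rest[:-1].split("("), None
        interval_str = span[0]
        strand = span[1] if len(span) > 1 else "+"
        lo, hi = (int(x) for x in interval_str.split("-"))
        seq = "".join(chunks).upper()
        records.append(
            PromoterRecord(gene_id, contig_id, (lo, hi), strand, seq, truncated=False)
        )

    with open(fasta_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                current_header = line[1:]
                chunks = []
            else:
                chunks.append(line.strip())
        flush()
    return records
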