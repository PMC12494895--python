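"""Genome container, gene models and FASTA/GFF3 round-trip I/O.

A :class:`GeneModel` carries the coordinates and coding-strand CDS sequence
of one ORF plus its selection-target length ``N`` — the CDS length plus a
regulatory allowance of 500 bp on each side, the window within which
mutations are attributed to the gene.

Coordinate conventions: GFF3 and all gene coordinates are 1-based inclusive;
depth tracks elsewhere in the package are 0-based half-open (bedGraph).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import CoordinateError, ValidationError

#: bp of regulatory sequence counted on *each* side of a CDS.
REGULATORY_FLANK = 500


@dataclass(frozen=True)
class GeneModel:
    """One protein-coding gene with its selection-target window.

    ``cds_sequence`` is always the coding-strand (sense) sequence; for a
    minus-strand gene it is the reverse complement of the plus-strand slice
    ``[cds_start, cds_end]``.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_start: int  # 1-based inclusive
    cds_end: int    # 1-based inclusive
    cds_sequence: str
    regulatory_flank: int = REGULATORY_FLANK

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.cds_end < self.cds_start:
            raise CoordinateError(
                f"{self.gene_id}: cds_end {self.cds_end} < cds_start {self.cds_start}"
            )
        if self.cds_length % 3 != 0:
            raise ValidationError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )
        if len(self.cds_sequence) != self.cds_length:
            raise ValidationError(
                f"{self.gene_id}: cds_sequence length {len(self.cds_sequence)} "
                f"!= coordinate span {self.cds_length}"
            )

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start + 1

    @property
    def target_length_N(self) -> int:
        """CDS length + 1000 bp regulatory allowance (500 bp per side)."""
        return self.cds_length + 2 * self.regulatory_flank

    @property
    def span_start(self) -> int:
        """1-based start of the CDS+regulatory window (may extend past the contig)."""
        return self.cds_start - self.regulatory_flank

    @property
    def span_end(self) -> int:
        return self.cds_end + self.regulatory_flank


@dataclass
class Genome:
    """Contig sequences plus the gene annotation living on them."""

    contigs: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.chrom not in self.contigs:
                raise CoordinateError(f"{g.gene_id}: unknown contig {g.chrom!r}")
            if g.cds_end > len(self.contigs[g.chrom]):
                raise CoordinateError(
                    f"{g.gene_id}: CDS end {g.cds_end} beyond contig "
                    f"{g.chrom} length {len(self.contigs[g.chrom])}"
                )

    @property
    def coding_bp(self) -> int:
        """Total selection-target bp: Σ over genes of (CDS + 1000)."""
        return sum(g.target_length_N for g in self.genes)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def cds_sequence_from_contig(contig: str, strand: str, start: int, end: int) -> str:
    """Extract the coding-strand CDS sequence from a plus-strand contig."""
    s = contig[start - 1 : end]
    return str(Seq(s).reverse_complement()) if strand == "-" else s


def write_fasta(genome: Genome, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in genome.contigs.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for g in sorted(genome.genes, key=lambda g: (g.chrom, g.cds_start)):
            fh.write(
                f"{g.chrom}\tevorepair\tCDS\t{g.cds_start}\t{g.cds_end}\t.\t"
                f"{g.strand}\t0\tID={g.gene_id}\n"
            )


def read_gff3(path, contigs: dict[str, str]) -> list[GeneModel]:
    """Parse CDS features from a minimal GFF3; sequences come from ``contigs``."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValidationError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != "CDS":
                continue
            gene_id = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
            if gene_id is None:
                raise ValidationError(f"{path}:{lineno}: CDS feature lacks ID attribute")
            if chrom not in contigs:
                raise CoordinateError(f"{path}:{lineno}: unknown contig {chrom!r}")
            start_i, end_i = int(start), int(end)
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    cds_start=start_i,
                    cds_end=end_i,
                    cds_sequence=cds_sequence_from_contig(
                        contigs[chrom], strand, start_i, end_i
                    ),
                )
            )
    return genes


def read_genome(fasta_path, gff_path) -> Genome:
    contigs = read_fasta(fasta_path)
    return Genome(contigs=contigs, genes=read_gff3(gff_path, contigs))


def genes_as_frame(genes: list[GeneModel]) -> pd.DataFrame:
    """Tabular view of an annotation (one row per gene)."""
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "cds_start": [g.cds_start for g in genes],
            "cds_end": [g.cds_end for g in genes],
            "cds_length": [g.cds_length for g in genes],
            "target_length_N": [g.target_length_N for g in genes],
        }
    )
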