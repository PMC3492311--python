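"""Gene models, reference access, and transcript<->genome coordinates.

Conventions: genomic intervals are 0-based half-open (BED/pysam style);
transcript coordinates are 1-based, which keeps variant notation readable
(a substitution at transcript position 434 is written A434T).  One record
models one transcript; isoforms are distinct records.
"""

from __future__ import annotations

import bisect
import dataclasses
import itertools
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

from .colorspace import reverse_complement

__all__ = [
    "GeneModel",
    "Genome",
    "load_gene_models",
    "write_gene_models",
    "transcript_seq",
    "transcript_to_genome",
    "genome_to_transcript",
    "merged_exon_length",
    "transcript_genomic_positions",
]


@dataclasses.dataclass(frozen=True)
class GeneModel:
    """A single-transcript gene model.

    ``exons`` are genomic intervals in ascending genomic order regardless of
    strand.  ``cds_start_tpos`` is the 1-based transcript coordinate of the
    first coding base, or 0 for a non-coding transcript.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start_tpos: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: no exons")
        prev_end = -1
        for start, end in self.exons:
            if not (0 <= start < end):
                raise ValueError(f"{self.gene_id}: bad exon [{start},{end})")
            if start < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = end
        if not (0 <= self.cds_start_tpos <= self.transcript_length):
            raise ValueError(f"{self.gene_id}: cds_start_tpos out of range")

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


class Genome:
    """In-memory reference: mapping of sequence name to DNA string."""

    def __init__(self, sequences: Mapping[str, str]):
        self.sequences = {name: str(seq).upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str) -> "Genome":
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")})

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def to_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def _cds_start_tpos(
    strand: str, exons: tuple[tuple[int, int], ...], thick_start: int, thick_end: int
) -> int:
    if thick_start >= thick_end:
        return 0
    first_coding_gpos = thick_start if strand == "+" else thick_end - 1
    gene = GeneModel("_tmp", "_", strand, exons, 0)
    tpos = genome_to_transcript(gene, "_", first_coding_gpos)
    if tpos is None:
        raise ValueError("thickStart/thickEnd does not fall in an exon")
    return tpos


def load_gene_models(path: str) -> list[GeneModel]:
    """Load gene models from BED12.

    Exon intervals come from blockSizes/blockStarts; thickStart/thickEnd are
    converted to the transcript coordinate of the first coding base (for a
    minus-strand record that is thickEnd-1 on the genome).  Malformed lines
    raise ``ValueError`` with the line number.
    """
    models: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED columns")
            try:
                chrom = fields[0]
                chrom_start, chrom_end = int(fields[1]), int(fields[2])
                name = fields[3]
                strand = fields[5]
                thick_start, thick_end = int(fields[6]), int(fields[7])
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if len(sizes) != block_count or len(starts) != block_count:
                raise ValueError(
                    f"{path}:{lineno}: blockCount {block_count} does not match "
                    f"blockSizes/blockStarts"
                )
            exons = tuple(
                (chrom_start + off, chrom_start + off + size)
                for off, size in zip(starts, sizes)
            )
            if exons[-1][1] != chrom_end:
                raise ValueError(
                    f"{path}:{lineno}: blocks do not span chromEnd"
                )
            try:
                cds = _cds_start_tpos(strand, exons, thick_start, thick_end)
                models.append(GeneModel(name, chrom, strand, exons, cds))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return models


def write_gene_models(path: str, genes: Iterable[GeneModel]) -> None:
    """Write gene models as BED12.

    The thick region runs from the first coding base to the transcript 3'
    end (the stop position is not modeled); non-coding records get a
    zero-length thick region at chromStart.
    """
    with open(path, "w") as fh:
        for g in genes:
            if g.cds_start_tpos:
                first_g = transcript_to_genome(g, g.cds_start_tpos)[1]
                if g.strand == "+":
                    thick = (first_g, g.end)
                else:
                    thick = (g.start, first_g + 1)
            else:
                thick = (g.start, g.start)
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, e in g.exons)
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            g.chrom, g.start, g.end, g.gene_id, 0, g.strand,
                            thick[0], thick[1], "0,0,0", len(g.exons),
                            sizes, starts,
                        ],
                    )
                )
                + "\n"
            )


def transcript_seq(genome: Genome, gene: GeneModel) -> str:
    """Spliced transcript sequence, 5'->3' in transcript orientation."""
    chrom_seq = genome[gene.chrom]
    if gene.end > len(chrom_seq):
        raise ValueError(
            f"{gene.gene_id}: exon beyond end of {gene.chrom} "
            f"({gene.end} > {len(chrom_seq)})"
        )
    spliced = "".join(chrom_seq[s:e] for s, e in gene.exons)
    return spliced if gene.strand == "+" else reverse_complement(spliced)


def _cum_lengths(gene: GeneModel) -> list[int]:
    return list(itertools.accumulate(e - s for s, e in gene.exons))


def transcript_to_genome(gene: GeneModel, tpos: int) -> tuple[str, int, str]:
    """Map a 1-based transcript coordinate to (chrom, 0-based gpos, strand)."""
    length = gene.transcript_length
    if not (1 <= tpos <= length):
        raise ValueError(
            f"{gene.gene_id}: tpos {tpos} outside transcript [1,{length}]"
        )
    # offset along the genomic (plus-strand) order of spliced positions
    offset = tpos - 1 if gene.strand == "+" else length - tpos
    cum = _cum_lengths(gene)
    exon_i = bisect.bisect_right(cum, offset)
    within = offset - (cum[exon_i - 1] if exon_i else 0)
    return gene.chrom, gene.exons[exon_i][0] + within, gene.strand


def genome_to_transcript(gene: GeneModel, chrom: str, gpos: int) -> int | None:
    """Inverse of :func:`transcript_to_genome`; None for non-exonic input."""
    if chrom != gene.chrom:
        return None
    offset = 0
    for start, end in gene.exons:
        if start <= gpos < end:
            offset += gpos - start
            break
        offset += end - start
    else:
        return None
    if gene.strand == "+":
        return offset + 1
    return gene.transcript_length - offset


def merged_exon_length(gene: GeneModel) -> int:
    """Total exonic bases — the "kilobase of exon" FPKM denominator."""
    return gene.transcript_length


def transcript_genomic_positions(gene: GeneModel) -> np.ndarray:
    """Genomic position of every transcript base, indexed by tpos-1."""
    parts = [np.arange(s, e, dtype=np.int64) for s, e in gene.exons]
    pos = np.concatenate(parts)
    return pos if gene.strand == "+" else pos[::-1].copy()
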