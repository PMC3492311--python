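"""attB junction detection and genomic fusion-coordinate resolution.

Each integrated cDNA is flanked by Gateway attB sequence, so a read that
crosses the vector/cDNA boundary carries a fixed 17-mer anchor
(``TTGTACAAAAAAGTTGG``), a fixed 22-base spacer, and then the first bases
of the insert.  Detecting the anchor (in base space or directly in SOLiD
color space), locating the first cDNA base in the read, and projecting that
position through the read's alignment — honoring soft clips, splice gaps
and reverse-strand mappings — yields the genomic fusion coordinate of the
insert.  Distinct coordinates within one gene indicate independent
full-length transcripts that differ in 5' UTR length.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, NamedTuple, Sequence

import pandas as pd
import pysam

from .colorspace import (
    ATTB_ANCHOR,
    ColorRead,
    attb_color_patterns,
    encode_colorspace,
    match_colors,
    reverse_complement,
)
from .refmodel import GeneModel, genome_to_transcript
from .screen_sim import ATTB1_SUFFIX

logger = logging.getLogger(__name__)

__all__ = [
    "Read",
    "JunctionHit",
    "FusionSite",
    "load_fastq",
    "demultiplex",
    "detect_attb",
    "resolve_fusion_coordinate",
    "aggregate_fusion_sites",
    "write_fusion_bed",
]


class Read(NamedTuple):
    read_id: str
    seq: str


@dataclasses.dataclass(frozen=True)
class JunctionHit:
    """An attB anchor occurrence in a read.

    ``cdna_offset`` is the 0-based read position of the first cDNA base
    (the base adjacent to the attB1 spacer).  For reverse-orientation hits
    the cDNA extends toward the read start.  ``partial`` marks hits whose
    spacer or first cDNA base falls off the read end.
    """

    read_id: str
    side: str
    orientation: str
    cdna_offset: int
    space: str
    library_id: str | None = None
    partial: bool = False


@dataclasses.dataclass(frozen=True)
class FusionSite:
    """Resolved genomic coordinate of an insert's first cDNA base."""

    gene_id: str
    chrom: str
    gpos: int
    strand: str
    read_count: int = 1


def load_fastq(path: str) -> list[Read]:
    from Bio import SeqIO

    return [Read(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fastq")]


def _strip_mate_suffix(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


def demultiplex(
    reads: Iterable[Read | ColorRead],
    barcode_table: dict[str, str],
    max_mismatch: int = 0,
) -> tuple[dict[str, list], list]:
    """Bin reads by barcode prefix (Hamming distance <= max_mismatch).

    Ambiguous assignments (ties at max_mismatch > 0) and non-matching reads
    go to the unassigned list; the barcode is not trimmed, so downstream
    read coordinates remain consistent with alignments of the full read.
    """
    lens = {len(b) for b in barcode_table.values()}
    if len(lens) != 1:
        raise ValueError("barcodes must have equal length")
    blen = lens.pop()
    assigned: dict[str, list] = {lib: [] for lib in barcode_table}
    unassigned: list = []
    for read in reads:
        seq = read.decode() if isinstance(read, ColorRead) else read.seq
        prefix = seq[:blen]
        best: list[str] = []
        best_d = max_mismatch + 1
        for lib, bc in barcode_table.items():
            d = sum(a != b for a, b in zip(prefix, bc))
            if d < best_d:
                best, best_d = [lib], d
            elif d == best_d:
                best.append(lib)
        if len(best) == 1 and best_d <= max_mismatch:
            assigned[best[0]].append(read)
        else:
            unassigned.append(read)
    n_un = len(unassigned)
    if n_un:
        logger.info("demultiplex: %d reads unassigned", n_un)
    return assigned, unassigned


def _find_approx(hay: str, needle: str, maxmm: int) -> list[int]:
    if maxmm == 0:
        out, start = [], 0
        while True:
            i = hay.find(needle, start)
            if i < 0:
                return out
            out.append(i)
            start = i + 1
    out = []
    n, m = len(hay), len(needle)
    for i in range(n - m + 1):
        mism = 0
        for a, b in zip(hay[i : i + m], needle):
            if a != b:
                mism += 1
                if mism > maxmm:
                    break
        else:
            out.append(i)
    return out


def _hits_base(
    read_id: str, seq: str, anchor: str, suffix: str, maxmm: int,
    library_id: str | None,
) -> list[JunctionHit]:
    hits = []
    L = len(seq)
    la, ls = len(anchor), len(suffix)
    for p in _find_approx(seq, anchor, maxmm):
        e = p + la
        avail = min(ls, L - e)
        if seq[e : e + avail] != suffix[:avail]:
            continue
        partial = avail < ls
        hits.append(JunctionHit(read_id, "attB1", "forward", e + ls, "base",
                                library_id, partial))
    rc_anchor = reverse_complement(anchor)
    rc_suffix = reverse_complement(suffix)
    for p in _find_approx(seq, rc_anchor, maxmm):
        lo = p - ls
        avail = min(ls, p)
        # in-read tail of the reverse-complemented spacer, ending at p
        if seq[p - avail : p] != rc_suffix[ls - avail :]:
            continue
        partial = lo - 1 < 0
        hits.append(JunctionHit(read_id, "attB1", "reverse", lo - 1, "base",
                                library_id, partial))
    hits.sort(key=lambda h: h.cdna_offset)
    return hits


def _hits_color(
    read: ColorRead, anchor: str, suffix: str, maxmm: int,
    library_id: str | None,
) -> list[JunctionHit]:
    fwd_pat, _ = attb_color_patterns(anchor)
    suffix_pat = encode_colorspace(anchor[-1] + suffix)  # 22 colors
    colors = read.colors
    L = len(colors)  # read base length under primer-anchored encoding
    la, ls = len(anchor), len(suffix)
    hits = []
    for c, orient in match_colors(read, fwd_pat, maxmm):
        p = c - 1  # base offset of anchor start in the read
        if p < 0:
            continue
        if orient == "forward":
            e = p + la
            # spacer colors start at the anchor/spacer transition (index e)
            avail = min(ls, L - e)
            if colors[e : e + avail] != suffix_pat[:avail]:
                continue
            hits.append(JunctionHit(read.read_id, "attB1", "forward",
                                    e + ls, "color", library_id, avail < ls))
        else:
            lo = p - ls
            avail = min(ls, p)
            window = colors[p + 1 - avail : p + 1]
            if window != suffix_pat[:avail][::-1]:
                continue
            hits.append(JunctionHit(read.read_id, "attB1", "reverse",
                                    lo - 1, "color", library_id, lo - 1 < 0))
    hits.sort(key=lambda h: h.cdna_offset)
    return hits


def detect_attb(
    read: Read | ColorRead,
    anchor_seq: str = ATTB_ANCHOR,
    space: str = "base",
    max_mismatches: int = 0,
    library_id: str | None = None,
) -> list[JunctionHit]:
    """Find attB1 junctions in one read, either orientation.

    In base space the anchor (and its reverse complement) is searched
    directly; in color space the search runs on the read's color string
    using the forward pattern and its reversal.  The fixed 22-base spacer
    between anchor and cDNA is verified where it lies within the read; a
    hit whose spacer or first cDNA base runs off the read is flagged
    partial (it cannot be resolved to a coordinate).
    """
    if space == "base":
        if isinstance(read, ColorRead):
            read = Read(read.read_id, read.decode())
        return _hits_base(read.read_id, read.seq, anchor_seq, ATTB1_SUFFIX,
                          max_mismatches, library_id)
    if space == "color":
        if not isinstance(read, ColorRead):
            raise TypeError("color-space detection requires a ColorRead")
        return _hits_color(read, anchor_seq, ATTB1_SUFFIX, max_mismatches,
                           library_id)
    raise ValueError(f"unknown space {space!r}")


_CONSUMES_QUERY = {0, 1, 4, 7, 8}  # M I S = X
_CONSUMES_REF = {0, 2, 3, 7, 8}  # M D N = X


def _query_to_ref(aln: pysam.AlignedSegment, qpos: int) -> int | None:
    """Reference coordinate of SAM query offset ``qpos`` via a CIGAR walk.

    Returns None when the position falls in a soft clip or insertion
    (unresolvable to the reference).
    """
    q, r = 0, aln.reference_start
    for op, ln in aln.cigartuples:
        cq, cr = op in _CONSUMES_QUERY, op in _CONSUMES_REF
        if cq and q <= qpos < q + ln:
            return r + (qpos - q) if cr else None
        if cq:
            q += ln
        if cr:
            r += ln
    return None


def resolve_fusion_coordinate(
    hit: JunctionHit,
    alignment: pysam.AlignedSegment,
    genes: Sequence[GeneModel],
    min_flank: int = 5,
    max_gene_distance: int = 1000,
) -> FusionSite | None:
    """Project a junction hit through its read's alignment to the genome.

    The first-cDNA-base read offset is mapped through the CIGAR (reversing
    read coordinates for reverse-strand alignments); the fusion strand
    combines hit orientation with alignment strand.  Returns None (with a
    warning) when the read carries fewer than ``min_flank`` cDNA bases, the
    hit is partial, or the base lands in a clip/insertion.
    """
    base_qname = _strip_mate_suffix(hit.read_id)
    if _strip_mate_suffix(alignment.query_name) != base_qname:
        raise ValueError(
            f"alignment {alignment.query_name} does not match hit {hit.read_id}"
        )
    if hit.partial or alignment.is_unmapped or not alignment.cigartuples:
        return None
    L = alignment.query_length
    # the first min_flank cDNA bases (away from the flank) must all be
    # aligned: rejects junction reads whose cDNA tail is too short to map
    # and sub-min_flank alignments whose strand is ambiguous
    step = 1 if hit.orientation == "forward" else -1
    window = range(hit.cdna_offset, hit.cdna_offset + step * min_flank, step)
    gpos: int | None = None
    for read_off in window:
        if not (0 <= read_off < L):
            return None
        qpos = read_off if not alignment.is_reverse else L - 1 - read_off
        ref = _query_to_ref(alignment, qpos)
        if ref is None:
            logger.warning("hit %s: cDNA base at read offset %d unaligned "
                           "(clip/insertion), unresolvable",
                           hit.read_id, read_off)
            return None
        if read_off == hit.cdna_offset:
            gpos = ref
    assert gpos is not None
    strand = "+" if (hit.orientation == "forward") == (not alignment.is_reverse) else "-"
    chrom = alignment.reference_name
    gene_id = assign_gene(chrom, gpos, genes, max_gene_distance)
    return FusionSite(gene_id, chrom, gpos, strand, 1)


def assign_gene(
    chrom: str, gpos: int, genes: Sequence[GeneModel], max_distance: int = 1000
) -> str:
    """Gene whose exons contain the coordinate, else nearest within
    ``max_distance`` bp (5' extensions land just outside exon 1), else
    "unassigned"."""
    best, best_d = "unassigned", max_distance + 1
    for g in genes:
        if g.chrom != chrom:
            continue
        if genome_to_transcript(g, chrom, gpos) is not None:
            return g.gene_id
        d = max(g.start - gpos, gpos - (g.end - 1), 0)
        if d < best_d:
            best, best_d = g.gene_id, d
    return best if best_d <= max_distance else "unassigned"


def aggregate_fusion_sites(
    sites: Iterable[FusionSite],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse per-read sites on exact (chrom, gpos, strand) identity.

    Returns (site table, per-gene summary).  Site rows are sorted by
    supporting read count descending, then coordinate; the summary gives
    distinct-site and total-read counts per gene.
    """
    rows = [dataclasses.asdict(s) for s in sites]
    cols = ["gene_id", "chrom", "gpos", "strand", "read_count"]
    if not rows:
        empty = pd.DataFrame(columns=cols)
        return empty, pd.DataFrame(columns=["gene_id", "distinct_sites",
                                            "total_reads"])
    df = pd.DataFrame(rows)
    grouped = (
        df.groupby(["gene_id", "chrom", "gpos", "strand"], as_index=False)
        ["read_count"].sum()
    )
    grouped = grouped.sort_values(
        ["read_count", "chrom", "gpos"], ascending=[False, True, True]
    ).reset_index(drop=True)[cols]
    summary = (
        grouped.groupby("gene_id", as_index=False)
        .agg(distinct_sites=("gpos", "size"), total_reads=("read_count", "sum"))
        .sort_values(["total_reads", "gene_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return grouped, summary


def write_fusion_bed(path: str, site_table: pd.DataFrame) -> None:
    """Fusion sites as BED6+2 (name=gene, score=read count, +side +rank)."""
    with open(path, "w") as fh:
        for rank, row in enumerate(site_table.itertuples(index=False), 1):
            fh.write(
                f"{row.chrom}\t{row.gpos}\t{row.gpos + 1}\t{row.gene_id}\t"
                f"{row.read_count}\t{row.strand}\tattB1\t{rank}\n"
            )
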