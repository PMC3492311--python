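"""Gene-level quantification, variant annotation and driver nomination.

Implements the read-out side of the screen: per-gene fragment counting from
paired alignments, FPKM (fragments per kilobase of exon per million mapped
fragments) ranking, a naive pileup caller with variant allele fractions,
codon-level substitution consequences, exon-skip detection from splice
gaps, and the nomination rule that combines a deleterious event with high
expression or multiple independent integration sites.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio.Seq import Seq

from .colorspace import reverse_complement
from .refmodel import (
    GeneModel,
    Genome,
    genome_to_transcript,
    merged_exon_length,
    transcript_seq,
)

__all__ = [
    "GeneQuant",
    "PileupResult",
    "Consequence",
    "VariantCall",
    "ExonSkipEvent",
    "count_fragments",
    "compute_fpkm",
    "pileup_vaf",
    "annotate_substitution",
    "call_variants",
    "detect_exon_skips",
    "nominate_candidates",
]


@dataclasses.dataclass(frozen=True)
class GeneQuant:
    gene_id: str
    fragment_count: int
    exon_len: int
    fpkm: float
    rank: int


@dataclasses.dataclass(frozen=True)
class PileupResult:
    """Base counts at one genomic site; ``covered`` is False at zero depth."""

    chrom: str
    gpos: int
    ref: str
    alt: str | None
    depth: int
    alt_count: int
    vaf: float  # percent
    covered: bool


@dataclasses.dataclass(frozen=True)
class Consequence:
    kind: str  # synonymous | missense | nonsense | utr | noncoding
    codon_index: int | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None

    def __str__(self) -> str:
        if self.codon_index is None:
            return self.kind
        return f"{self.aa_ref}{self.codon_index}{self.aa_alt}"


@dataclasses.dataclass(frozen=True)
class VariantCall:
    gene_id: str
    tpos: int
    ref: str
    alt: str
    depth: int
    alt_count: int
    vaf: float  # percent
    consequence: Consequence


@dataclasses.dataclass(frozen=True)
class ExonSkipEvent:
    gene_id: str
    exon_index: int  # 1-based, transcript order
    junction_reads: int


def _is_primary(aln: pysam.AlignedSegment) -> bool:
    return not (aln.is_secondary or aln.is_supplementary or aln.is_duplicate)


class _ExonIndex:
    """Per-chromosome sorted exon arrays for fast overlap queries."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        per: dict[str, list[tuple[int, int, int]]] = {}
        for gi, g in enumerate(genes):
            for s, e in g.exons:
                per.setdefault(g.chrom, []).append((s, e, gi))
        for chrom, items in per.items():
            items.sort()
            starts = np.array([s for s, _, _ in items], dtype=np.int64)
            ends = np.array([e for _, e, _ in items], dtype=np.int64)
            gidx = np.array([g for _, _, g in items], dtype=np.int64)
            self.by_chrom[chrom] = (starts, ends, gidx)

    def overlap(self, chrom: str, bs: int, be: int, acc: dict[int, int]) -> None:
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return
        starts, ends, gidx = entry
        i1 = int(np.searchsorted(starts, be, side="left"))
        for i in range(i1 - 1, -1, -1):
            if ends[i] <= bs:
                # exons of different genes may interleave; scan a little
                # further back before giving up
                if starts[i] <= bs - 10_000:
                    break
                continue
            ov = min(be, int(ends[i])) - max(bs, int(starts[i]))
            if ov > 0:
                acc[int(gidx[i])] = acc.get(int(gidx[i]), 0) + ov


def count_fragments(
    alignments: Iterable[pysam.AlignedSegment],
    genes: Sequence[GeneModel],
) -> tuple[dict[str, int], int]:
    """Count fragments per gene by maximal exonic overlap.

    A fragment (read pair, or orphan single read) is counted once, for the
    gene with the largest exonic overlap of its aligned bases; ties and
    zero-overlap fragments stay unassigned but still count toward the
    mapped-fragment total.  Only primary alignments are considered; input
    order is irrelevant (records are buffered by read name).
    """
    index = _ExonIndex(genes)
    by_frag: dict[str, list[pysam.AlignedSegment]] = {}
    for aln in alignments:
        if not _is_primary(aln):
            continue
        qname = aln.query_name
        if qname.endswith(("/1", "/2")):
            qname = qname[:-2]
        by_frag.setdefault(qname, []).append(aln)
    counts: dict[str, int] = {}
    total_mapped = 0
    for records in by_frag.values():
        mapped = [a for a in records if not a.is_unmapped]
        if not mapped:
            continue
        total_mapped += 1
        overlap: dict[int, int] = {}
        for a in mapped:
            for bs, be in a.get_blocks():
                index.overlap(a.reference_name, bs, be, overlap)
        if not overlap:
            continue
        top = max(overlap.values())
        winners = [g for g, v in overlap.items() if v == top]
        if len(winners) == 1:
            gid = genes[winners[0]].gene_id
            counts[gid] = counts.get(gid, 0) + 1
    return counts, total_mapped


def compute_fpkm(
    counts: Mapping[str, int],
    genes: Sequence[GeneModel],
    total_mapped_fragments: int,
) -> list[GeneQuant]:
    """FPKM per gene: count x 10^9 / (merged exon length x total fragments).

    Every supplied gene gets a row (zero counts give FPKM 0); ranks are by
    descending FPKM with lexicographic gene-id tie-break.
    """
    if total_mapped_fragments <= 0:
        raise ValueError("total_mapped_fragments must be positive")
    rows = []
    for g in genes:
        exon_len = merged_exon_length(g)
        if exon_len == 0:
            raise ValueError(f"{g.gene_id}: zero exon length")
        n = int(counts.get(g.gene_id, 0))
        fpkm = n * 1e9 / (exon_len * total_mapped_fragments)
        rows.append((g.gene_id, n, exon_len, fpkm))
    rows.sort(key=lambda r: (-r[3], r[0]))
    return [
        GeneQuant(gid, n, el, fpkm, rank)
        for rank, (gid, n, el, fpkm) in enumerate(rows, 1)
    ]


def quant_table(quants: Sequence[GeneQuant]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(q) for q in quants],
        columns=["gene_id", "fragment_count", "exon_len", "fpkm", "rank"],
    )


def _query_base_at(aln: pysam.AlignedSegment, rpos: int) -> str | None:
    """Read base aligned to reference position ``rpos`` (None if not M)."""
    q, r = 0, aln.reference_start
    if rpos < r:
        return None
    for op, ln in aln.cigartuples:
        cq = op in (0, 1, 4, 7, 8)
        cr = op in (0, 2, 3, 7, 8)
        if cr and r <= rpos < r + ln:
            return aln.query_sequence[q + (rpos - r)] if cq else None
        if cq:
            q += ln
        if cr:
            r += ln
    return None


def pileup_vaf(
    alignments: Iterable[pysam.AlignedSegment],
    genome: Genome,
    site: tuple[str, int],
) -> PileupResult:
    """Depth, alternate count and percent VAF at one genomic site.

    Primary, non-duplicate alignments only; the alternate allele is the
    most frequent non-reference base.  Zero depth returns an explicit
    no-coverage result.
    """
    chrom, gpos = site
    ref = genome[chrom][gpos]
    tally: dict[str, int] = {}
    for aln in alignments:
        if aln.is_unmapped or not _is_primary(aln):
            continue
        if aln.reference_name != chrom:
            continue
        base = _query_base_at(aln, gpos)
        if base is not None:
            tally[base] = tally.get(base, 0) + 1
    depth = sum(tally.values())
    if depth == 0:
        return PileupResult(chrom, gpos, ref, None, 0, 0, 0.0, covered=False)
    non_ref = {b: n for b, n in tally.items() if b != ref}
    if non_ref:
        alt = max(sorted(non_ref), key=lambda b: non_ref[b])
        alt_count = non_ref[alt]
    else:
        alt, alt_count = None, 0
    return PileupResult(chrom, gpos, ref, alt, depth, alt_count,
                        100.0 * alt_count / depth, covered=True)


def annotate_substitution(
    gene: GeneModel | None,
    pos: int,
    ref: str,
    alt: str,
    sequence: str,
    *,
    pos_is_cds: bool = False,
) -> Consequence:
    """Codon-level consequence of a substitution.

    ``pos`` is a 1-based transcript coordinate and ``sequence`` the
    transcript sequence, unless ``pos_is_cds`` is set, in which case both
    are relative to the coding sequence itself (``gene`` may then be None).  The affected codon index
    is ``ceil(cds_pos / 3)``; translation uses the standard genetic code,
    with stop gains labeled nonsense.
    """
    if ref == alt:
        raise ValueError(f"ref and alt are both {ref!r}: not a variant")
    if not (1 <= pos <= len(sequence)):
        raise ValueError(f"position {pos} outside sequence of length {len(sequence)}")
    if sequence[pos - 1] != ref:
        raise ValueError(
            f"ref mismatch at position {pos}: sequence has "
            f"{sequence[pos - 1]!r}, expected {ref!r}"
        )
    if pos_is_cds:
        cds, cds_pos = sequence, pos
    else:
        if gene.cds_start_tpos == 0:
            return Consequence("noncoding")
        if pos < gene.cds_start_tpos:
            return Consequence("utr")
        cds = sequence[gene.cds_start_tpos - 1 :]
        cds_pos = pos - gene.cds_start_tpos + 1
    if cds_pos > (len(cds) // 3) * 3:
        return Consequence("utr")  # beyond the last complete codon
    codon_index = math.ceil(cds_pos / 3)
    cstart = (codon_index - 1) * 3
    codon = cds[cstart : cstart + 3]
    within = cds_pos - 1 - cstart
    alt_codon = codon[:within] + alt + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_alt == "*" and aa_ref != "*":
        kind = "nonsense"
    elif aa_ref == aa_alt:
        kind = "synonymous"
    else:
        kind = "missense"
    return Consequence(kind, codon_index, aa_ref, aa_alt)


def call_variants(
    alignments: Iterable[pysam.AlignedSegment],
    genome: Genome,
    genes: Sequence[GeneModel],
    min_depth: int = 10,
    min_alt_frac: float = 0.2,
) -> list[VariantCall]:
    """Naive pileup caller over all exonic positions of the given genes.

    Reports, per site passing depth and allele-fraction thresholds, the
    transcript-space alleles (complemented for minus-strand genes) with a
    codon-level consequence.
    """
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    per_chrom: dict[str, np.ndarray] = {}
    for chrom, seq in genome.sequences.items():
        per_chrom[chrom] = np.zeros((4, len(seq)), dtype=np.int32)
    for aln in alignments:
        if aln.is_unmapped or not _is_primary(aln):
            continue
        counts = per_chrom[aln.reference_name]
        seq = aln.query_sequence
        pairs = aln.get_aligned_pairs(matches_only=True)
        if not pairs:
            continue
        qpos = np.fromiter((p[0] for p in pairs), dtype=np.int64)
        rpos = np.fromiter((p[1] for p in pairs), dtype=np.int64)
        bidx = np.array([base_idx.get(seq[q], -1) for q in qpos], dtype=np.int64)
        ok = bidx >= 0
        np.add.at(counts, (bidx[ok], rpos[ok]), 1)
    calls: list[VariantCall] = []
    bases = "ACGT"
    for g in genes:
        counts = per_chrom[g.chrom]
        tseq = transcript_seq(genome, g)
        for s, e in g.exons:
            block = counts[:, s:e]
            depth = block.sum(axis=0)
            top_alt_possible = np.nonzero(depth >= min_depth)[0]
            for off in top_alt_possible:
                gpos = s + int(off)
                ref_g = genome[g.chrom][gpos]
                col = block[:, off]
                d = int(depth[off])
                alt_counts = {
                    bases[i]: int(col[i]) for i in range(4) if bases[i] != ref_g
                }
                alt_g = max(sorted(alt_counts), key=lambda b: alt_counts[b])
                n_alt = alt_counts[alt_g]
                if n_alt < min_alt_frac * d or n_alt == 0:
                    continue
                tpos = genome_to_transcript(g, g.chrom, gpos)
                if g.strand == "+":
                    ref_t, alt_t = ref_g, alt_g
                else:
                    ref_t = reverse_complement(ref_g)
                    alt_t = reverse_complement(alt_g)
                cons = annotate_substitution(g, tpos, ref_t, alt_t, tseq)
                calls.append(
                    VariantCall(g.gene_id, tpos, ref_t, alt_t, d, n_alt,
                                100.0 * n_alt / d, cons)
                )
    calls.sort(key=lambda c: (c.gene_id, c.tpos))
    return calls


def _splice_gaps(aln: pysam.AlignedSegment) -> list[tuple[int, int]]:
    gaps, r = [], aln.reference_start
    for op, ln in aln.cigartuples:
        if op == 3:  # N
            gaps.append((r, r + ln))
        if op in (0, 2, 3, 7, 8):
            r += ln
    return gaps


def detect_exon_skips(
    alignments: Iterable[pysam.AlignedSegment],
    gene: GeneModel,
    min_reads: int = 2,
) -> list[ExonSkipEvent]:
    """Internal exons skipped by splice gaps in the alignments.

    An exon k (1-based, transcript order) is called skipped when at least
    ``min_reads`` alignments carry an N gap running exactly from the 3' end
    of the genomically preceding exon to the 5' start of the following one;
    boundaries must match exactly (no fuzz).
    """
    gap_counts: dict[tuple[int, int], int] = {}
    for aln in alignments:
        if aln.is_unmapped or not _is_primary(aln):
            continue
        if aln.reference_name != gene.chrom:
            continue
        for gap in _splice_gaps(aln):
            gap_counts[gap] = gap_counts.get(gap, 0) + 1
    n = len(gene.exons)
    events = []
    for gi in range(1, n - 1):  # internal exons, genomic order
        expected = (gene.exons[gi - 1][1], gene.exons[gi + 1][0])
        reads = gap_counts.get(expected, 0)
        if reads >= min_reads:
            tindex = gi + 1 if gene.strand == "+" else n - gi
            events.append(ExonSkipEvent(gene.gene_id, tindex, reads))
    events.sort(key=lambda e: e.exon_index)
    return events


def nominate_candidates(
    quants: Sequence[GeneQuant],
    fusion_summary: pd.DataFrame,
    variants: Sequence[VariantCall],
    skips: Sequence[ExonSkipEvent],
    top_k: int = 10,
    min_sites: int = 3,
) -> pd.DataFrame:
    """Flag driver candidates.

    A gene is flagged iff it carries a deleterious event (non-synonymous
    variant or exon skip) AND is either in the FPKM top ``top_k`` or has at
    least ``min_sites`` distinct fusion sites.  Unflagged genes remain in
    the report as background (the highly expressed but unmutated
    housekeeping pattern).
    """
    sites = (
        dict(zip(fusion_summary["gene_id"], fusion_summary["distinct_sites"]))
        if len(fusion_summary)
        else {}
    )
    nonsyn: dict[str, list[str]] = {}
    for v in variants:
        if v.consequence.kind in ("missense", "nonsense"):
            nonsyn.setdefault(v.gene_id, []).append(str(v.consequence))
    skip_by_gene: dict[str, list[int]] = {}
    for ev in skips:
        skip_by_gene.setdefault(ev.gene_id, []).append(ev.exon_index)
    rows = []
    for q in quants:
        g = q.gene_id
        n_sites = int(sites.get(g, 0))
        reasons = []
        has_event = False
        if g in nonsyn:
            has_event = True
            reasons.append("nonsynonymous:" + ",".join(nonsyn[g]))
        if g in skip_by_gene:
            has_event = True
            reasons.append(
                "exon_skip:" + ",".join(f"exon{k}" for k in skip_by_gene[g])
            )
        context = []
        if q.rank <= top_k:
            context.append(f"fpkm_rank<={top_k}")
        if n_sites >= min_sites:
            context.append(f"fusion_sites>={min_sites}")
        flagged = has_event and bool(context)
        rows.append(
            {
                "gene_id": g,
                "fpkm": q.fpkm,
                "fpkm_rank": q.rank,
                "distinct_fusion_sites": n_sites,
                "n_nonsyn_variants": len(nonsyn.get(g, [])),
                "n_exon_skips": len(skip_by_gene.get(g, [])),
                "flagged": flagged,
                "reasons": ";".join(reasons + context) if flagged else "",
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "fpkm", "fpkm_rank", "distinct_fusion_sites",
            "n_nonsyn_variants", "n_exon_skips", "flagged", "reasons",
        ],
    )
    return df.sort_values(["flagged", "fpkm"], ascending=[False, False]).reset_index(
        drop=True
    )
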