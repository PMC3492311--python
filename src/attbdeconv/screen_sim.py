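"""Synthetic screen generator: pooled clones carrying attB-flanked cDNAs.

Emulates a pooled gain-of-function cDNA screen read out by sequencing: each
surviving clone of an IL3-dependent reporter line carries several
retrovirally integrated, attB-flanked, 5'-truncated full-length cDNAs.  Per
library the integrated amplicons are concatenated in random order and
orientation, sheared into fragments, and sequenced as asymmetric paired
reads (75 + 35 bases by default) with a per-library barcode on read 1.

Every read is emitted together with its ground-truth alignment (SAM, with
soft clips over vector/adjacent-amplicon bases and N operations across
introns), and the generator records ground-truth insert composition and
per-gene fragment counts so downstream detection, counting and annotation
can be validated exactly.

A "driver" insert can be planted into every clone of designated libraries,
cycling through a fixed set of 5' truncation points — modeling the
selection step, in which every surviving clone carries the transforming
cDNA and independent full-length transcripts differ in 5' UTR length.
"""

from __future__ import annotations

import dataclasses
import random
import sys
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .colorspace import ColorRead, encode_colorspace, reverse_complement, write_color_file
from .refmodel import (
    GeneModel,
    Genome,
    transcript_genomic_positions,
    transcript_seq,
)

__all__ = [
    "ATTB1_FLANK",
    "ATTB2_FLANK",
    "ATTB1_SUFFIX",
    "InsertSpec",
    "InsertTruth",
    "SimConfig",
    "SimBundle",
    "CoveragePlan",
    "plan_coverage",
    "default_barcodes",
    "synthetic_reference",
    "build_amplicon",
    "simulate_screen",
]

#: attB1-side flank: the attB1_forward PCR primer.  Contains the 17-mer
#: junction anchor followed by a fixed 22-base spacer before the cDNA.
ATTB1_FLANK = "GGGGACAACTTTGTACAAAAAAGTTGGAAGCAGTGGTATCAACGCAGAG"
#: attB2-side flank: the attB2_reverse PCR primer (amplicon ends with its
#: reverse complement).
ATTB2_FLANK = "CCGCACAACTTTGTACAAGAAAGTTGGGTCGGGGTACGATGAGACACCA"
#: Fixed flank sequence between the attB1 anchor and the first cDNA base.
ATTB1_SUFFIX = ATTB1_FLANK[27:]

assert ATTB1_FLANK[10:27] == "TTGTACAAAAAAGTTGG"


@dataclasses.dataclass(frozen=True)
class InsertSpec:
    """Template for drawing inserts of one gene into clones.

    ``variants`` are (tpos, alt) substitutions on the transcript;
    ``skipped_exons`` are 1-based transcript exon indices (internal exons);
    ``trunc_choices``, when given, restricts 5' truncation points to a fixed
    set instead of drawing uniformly over the 5' UTR.
    """

    gene_id: str
    variants: tuple[tuple[int, str], ...] = ()
    skipped_exons: tuple[int, ...] = ()
    weight: float = 1.0
    trunc_choices: tuple[int, ...] | None = None


@dataclasses.dataclass(frozen=True)
class InsertTruth:
    """Ground truth for one integrated insert."""

    library_id: str
    clone_id: str
    gene_id: str
    trunc_tpos: int
    variants: tuple[tuple[int, str, str], ...]  # (tpos, ref, alt)
    skipped_exons: tuple[int, ...]
    amplicon_len: int


@dataclasses.dataclass(frozen=True)
class CoveragePlan:
    total_cdna_bp: float
    fold_coverage: float


def plan_coverage(
    n_specimens: int,
    clones_per_specimen: int,
    inserts_per_clone: int,
    mean_insert_bp: int,
    sequenced_bp: float,
) -> CoveragePlan:
    """Sequencing-design arithmetic for a pooled screen.

    total cDNA = specimens x clones x inserts x mean insert length;
    fold coverage = sequenced bases / total cDNA.
    """
    args = (n_specimens, clones_per_specimen, inserts_per_clone,
            mean_insert_bp, sequenced_bp)
    if any(a <= 0 for a in args):
        raise ValueError("all coverage-plan inputs must be positive")
    total = n_specimens * clones_per_specimen * inserts_per_clone * mean_insert_bp
    return CoveragePlan(float(total), sequenced_bp / total)


def default_barcodes(n: int, length: int = 6, seed: int = 7) -> list[str]:
    """Deterministic unique barcodes with pairwise Hamming distance >= 3."""
    rng = random.Random(seed)
    chosen: list[str] = []
    attempts = 0
    while len(chosen) < n:
        cand = "".join(rng.choice("ACGT") for _ in range(length))
        if all(
            sum(a != b for a, b in zip(cand, c)) >= 3 for c in chosen
        ):
            chosen.append(cand)
        attempts += 1
        if attempts > 100000:
            raise ValueError(f"cannot build {n} barcodes of length {length}")
    return chosen


@dataclasses.dataclass
class SimConfig:
    """Study conditions of the simulated screen.

    Defaults mirror the screen design: 21 libraries, ~10 surviving clones
    per library, Poisson(7) inserts per clone (minimum 1), 75+35 paired
    reads, 500+/-100 bp shear size (floor 150), 6-bp library barcodes
    prefixed to read 1, no sequencing error.
    """

    n_libraries: int = 21
    clones_per_library: int = 10
    inserts_per_clone_mean: float = 7.0
    insert_pool: tuple[InsertSpec, ...] = ()
    fragment_length_mean: float = 500.0
    fragment_length_sd: float = 100.0
    fragment_length_min: int = 150
    read_lengths: tuple[int, int] = (75, 35)
    barcode_table: dict[str, str] | None = None
    barcode_length: int = 6
    fragments_per_library: int = 5000
    error_rate: float = 0.0
    space: str = "base"
    seed: int = 0
    driver: InsertSpec | None = None
    driver_libraries: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if min(self.n_libraries, self.clones_per_library,
               self.fragments_per_library) < 1:
            raise ValueError("counts must be >= 1")
        if self.inserts_per_clone_mean < 1:
            raise ValueError("inserts_per_clone_mean must be >= 1")
        if not (0.0 <= self.error_rate < 0.25):
            raise ValueError("error_rate must be in [0, 0.25)")
        if self.space not in ("base", "color"):
            raise ValueError("space must be 'base' or 'color'")
        if self.driver is not None and not self.driver.trunc_choices:
            raise ValueError("driver insert needs explicit trunc_choices")

    def library_ids(self) -> list[str]:
        return [f"lib{i + 1:02d}" for i in range(self.n_libraries)]

    def resolved_barcodes(self) -> dict[str, str]:
        if self.barcode_table is not None:
            bcs = self.barcode_table
        else:
            codes = default_barcodes(
                self.n_libraries, self.barcode_length, seed=self.seed % (2**31)
            )
            bcs = dict(zip(self.library_ids(), codes))
        vals = list(bcs.values())
        if len(set(vals)) != len(vals) or len({len(v) for v in vals}) != 1:
            raise ValueError("barcodes must be unique and of equal length")
        return bcs


@dataclasses.dataclass
class SimBundle:
    """File paths and in-memory truth produced by one simulation run."""

    out_dir: Path
    reads1: Path
    reads2: Path
    truth_sam: Path
    truth_inserts: Path
    truth_counts: Path
    barcodes: Path
    inserts: list[InsertTruth]
    counts: dict[tuple[str, str], int]
    total_mapped: dict[str, int]
    junctions: dict[tuple[str, int, str], str]  # (chrom,gpos,strand) -> gene


def synthetic_reference(
    n_genes: int = 30,
    seed: int = 0,
    chrom: str = "chr1",
    n_exons: tuple[int, int] = (3, 8),
    exon_len: tuple[int, int] = (90, 250),
    intron_len: tuple[int, int] = (60, 300),
    utr5_len: tuple[int, int] = (120, 350),
) -> tuple[Genome, list[GeneModel]]:
    """Random multi-exon reference for simulations and tests.

    Genes are laid out on one chromosome with 500-bp gaps, alternating in
    strand; the 5' UTR length sets the coding start and leaves room for
    variable 5' truncation points.
    """
    rng = random.Random(seed)
    seq_parts: list[str] = []
    genes: list[GeneModel] = []
    cursor = 0
    for gi in range(n_genes):
        gap = "".join(rng.choice("ACGT") for _ in range(500))
        seq_parts.append(gap)
        cursor += len(gap)
        k = rng.randint(*n_exons)
        exons = []
        pos = cursor
        for ei in range(k):
            elen = rng.randint(*exon_len)
            exons.append((pos, pos + elen))
            pos += elen
            if ei < k - 1:
                pos += rng.randint(*intron_len)
        body_len = pos - cursor
        seq_parts.append("".join(rng.choice("ACGT") for _ in range(body_len)))
        cursor = pos
        strand = "+" if gi % 2 == 0 else "-"
        tlen = sum(e - s for s, e in exons)
        utr5 = min(rng.randint(*utr5_len), max(1, tlen // 3))
        genes.append(
            GeneModel(f"GENE{gi + 1:03d}", chrom, strand, tuple(exons), utr5 + 1)
        )
    seq_parts.append("".join(rng.choice("ACGT") for _ in range(500)))
    genome = Genome({chrom: "".join(seq_parts)})
    return genome, genes


def _transcript_exon_spans(gene: GeneModel) -> list[tuple[int, int]]:
    """Half-open tpos-1 spans of each exon, in transcript order."""
    lens = [e - s for s, e in gene.exons]
    if gene.strand == "-":
        lens = lens[::-1]
    spans, off = [], 0
    for ln in lens:
        spans.append((off, off + ln))
        off += ln
    return spans


def _insert_cdna(
    genome: Genome, gene: GeneModel, insert: InsertTruth
) -> tuple[str, np.ndarray]:
    """cDNA sequence of an insert plus genomic position of every base."""
    tseq = list(transcript_seq(genome, gene))
    gpos = transcript_genomic_positions(gene)
    length = len(tseq)
    if not (1 <= insert.trunc_tpos <= length):
        raise ValueError(
            f"{gene.gene_id}: trunc_tpos {insert.trunc_tpos} out of range"
        )
    for tpos, ref, alt in insert.variants:
        if not (1 <= tpos <= length):
            raise ValueError(f"{gene.gene_id}: variant tpos {tpos} out of range")
        if tseq[tpos - 1] != ref:
            raise ValueError(
                f"{gene.gene_id}: variant ref mismatch at tpos {tpos}: "
                f"transcript has {tseq[tpos - 1]}, expected {ref}"
            )
        tseq[tpos - 1] = alt
    keep = np.ones(length, dtype=bool)
    keep[: insert.trunc_tpos - 1] = False
    spans = _transcript_exon_spans(gene)
    for k in insert.skipped_exons:
        if not (1 <= k <= len(spans)):
            raise ValueError(f"{gene.gene_id}: no exon {k}")
        s, e = spans[k - 1]
        keep[s:e] = False
    seq = "".join(b for b, m in zip(tseq, keep) if m)
    return seq, gpos[keep]


def build_amplicon(genome: Genome, gene: GeneModel, insert: InsertTruth) -> str:
    """PCR amplicon of one integrant: attB1 flank + cDNA + revcomp(attB2)."""
    cdna, _ = _insert_cdna(genome, gene, insert)
    return ATTB1_FLANK + cdna + reverse_complement(ATTB2_FLANK)


def _amplicon_arrays(
    genome: Genome, gene: GeneModel, gene_idx: int, insert: InsertTruth
) -> tuple[str, np.ndarray, np.ndarray, np.ndarray]:
    cdna, cdna_gpos = _insert_cdna(genome, gene, insert)
    seq = ATTB1_FLANK + cdna + reverse_complement(ATTB2_FLANK)
    gpos = np.full(len(seq), -1, dtype=np.int64)
    gpos[len(ATTB1_FLANK) : len(ATTB1_FLANK) + len(cdna)] = cdna_gpos
    gidx = np.full(len(seq), gene_idx, dtype=np.int32)
    # per-base genomic orientation: +1 when the amplicon base equals the
    # reference base at gpos, -1 when it is its complement (minus-strand
    # transcripts); disambiguates the strand of single-base aligned runs
    gdir = np.zeros(len(seq), dtype=np.int8)
    gdir[len(ATTB1_FLANK) : len(ATTB1_FLANK) + len(cdna)] = (
        1 if gene.strand == "+" else -1
    )
    return seq, gpos, gidx, gdir


def _longest_aligned_run(
    gpos: np.ndarray, inst: np.ndarray
) -> tuple[int, int] | None:
    """Longest contiguous stretch of aligned bases from one amplicon copy."""
    best: tuple[int, int] | None = None
    i, n = 0, len(gpos)
    while i < n:
        if gpos[i] < 0:
            i += 1
            continue
        j = i + 1
        while j < n and gpos[j] >= 0 and inst[j] == inst[i]:
            j += 1
        if best is None or j - i > best[1] - best[0]:
            best = (i, j)
        i = j
    return best


def _make_alignment(
    header: pysam.AlignmentHeader,
    qname: str,
    seq: str,
    gpos: np.ndarray,
    inst: np.ndarray,
    gdir: np.ndarray,
    is_read2: bool,
) -> pysam.AlignedSegment:
    """Truth SAM record: soft clips outside the chosen aligned run,
    N operations across introns, reverse-strand encoding when the run's
    genomic coordinates decrease along the read."""
    a = pysam.AlignedSegment(header)
    a.query_name = qname
    flag = 0x1 | (0x80 if is_read2 else 0x40)
    run = _longest_aligned_run(gpos, inst)
    length = len(seq)
    if run is None:
        a.flag = flag | 0x4
        a.query_sequence = seq
        a.query_qualities = pysam.qualitystring_to_array("?" * length)
        return a
    s, e = run
    g = gpos[s:e]
    reverse = gdir[s] < 0
    if reverse:
        flag |= 0x10
        seq_out = reverse_complement(seq)
        g = g[::-1]
        lead, trail = length - e, s
    else:
        seq_out = seq
        lead, trail = s, length - e
    cig: list[tuple[int, int]] = []
    if lead:
        cig.append((4, lead))  # S
    mlen = 1
    for i in range(1, len(g)):
        d = int(g[i] - g[i - 1])
        if d == 1:
            mlen += 1
        elif d > 1:
            cig.append((0, mlen))
            cig.append((3, d - 1))  # N
            mlen = 1
        else:  # pragma: no cover - monotonic within one amplicon copy
            raise AssertionError("non-monotonic truth coordinates in one run")
    cig.append((0, mlen))
    if trail:
        cig.append((4, trail))
    a.flag = flag
    a.reference_id = 0
    a.reference_start = int(g[0])
    a.mapping_quality = 60
    a.cigartuples = cig
    a.query_sequence = seq_out
    a.query_qualities = pysam.qualitystring_to_array("?" * length)
    return a


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    n_err = rng.binomial(len(arr), rate)
    for pos in rng.choice(len(arr), size=n_err, replace=False):
        alts = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = alts[rng.integers(0, 3)]
    return "".join(arr)


def simulate_screen(
    config: SimConfig,
    genome: Genome,
    genes: Sequence[GeneModel],
    out_dir: str | Path,
) -> SimBundle:
    """Run the full generative model and write reads + truth files.

    Deterministic under a fixed config/seed: two runs produce byte-identical
    outputs.  Per-gene truth fragment counts are derived from the generator's
    own per-base annotation (gene identity of each aligned read base,
    maximal-overlap assignment with ties unassigned), independently of any
    downstream SAM-based counter.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    gene_by_id = {g.gene_id: g for g in genes}
    gene_list = list(genes)
    gene_index = {g.gene_id: i for i, g in enumerate(gene_list)}
    pool = list(config.insert_pool)
    if not pool:
        raise ValueError("insert_pool is empty")
    for spec in pool + ([config.driver] if config.driver else []):
        if spec.gene_id not in gene_by_id:
            raise ValueError(f"insert pool gene {spec.gene_id} not in gene models")
    weights = np.array([s.weight for s in pool], dtype=float)
    weights /= weights.sum()
    barcodes = config.resolved_barcodes()
    read1_len, read2_len = config.read_lengths

    tseq_cache = {g.gene_id: transcript_seq(genome, g) for g in gene_by_id.values()}

    def draw_trunc(spec: InsertSpec) -> int:
        gene = gene_by_id[spec.gene_id]
        if spec.trunc_choices:
            return int(spec.trunc_choices[rng.integers(0, len(spec.trunc_choices))])
        hi = gene.cds_start_tpos if gene.cds_start_tpos > 1 else max(
            2, gene.transcript_length // 2
        )
        return int(rng.integers(1, hi + 1))

    def realize(spec: InsertSpec, lib: str, clone: str, trunc: int) -> InsertTruth:
        tseq = tseq_cache[spec.gene_id]
        variants = tuple(
            (tpos, tseq[tpos - 1], alt) for tpos, alt in spec.variants
        )
        return InsertTruth(lib, clone, spec.gene_id, trunc, variants,
                           spec.skipped_exons, 0)

    header = pysam.AlignmentHeader.from_references(
        list(genome.sequences.keys()), [len(s) for s in genome.sequences.values()]
    )

    ext = "csreads" if config.space == "color" else "fastq"
    paths = SimBundle(
        out_dir=out,
        reads1=out / f"reads_1.{ext}",
        reads2=out / f"reads_2.{ext}",
        truth_sam=out / "truth.sam",
        truth_inserts=out / "truth_inserts.tsv",
        truth_counts=out / "truth_counts.tsv",
        barcodes=out / "barcodes.tsv",
        inserts=[],
        counts={},
        total_mapped={},
        junctions={},
    )

    color1: list[ColorRead] = []
    color2: list[ColorRead] = []
    fq1 = open(paths.reads1, "w")
    fq2 = open(paths.reads2, "w")
    sam = pysam.AlignmentFile(str(paths.truth_sam), "w", header=header)
    counts: dict[tuple[str, str], int] = {}
    total_mapped: dict[str, int] = {}
    driver_cycle = 0

    try:
        for lib in config.library_ids():
            bc = barcodes[lib]
            amp_seqs: list[str] = []
            amp_gpos: list[np.ndarray] = []
            amp_gidx: list[np.ndarray] = []
            amp_gdir: list[np.ndarray] = []
            for ci in range(config.clones_per_library):
                clone = f"{lib}c{ci + 1:02d}"
                clone_specs: list[tuple[InsertSpec, int]] = []
                if config.driver is not None and lib in config.driver_libraries:
                    tc = config.driver.trunc_choices
                    clone_specs.append((config.driver, tc[driver_cycle % len(tc)]))
                    driver_cycle += 1
                n_ins = max(1, int(rng.poisson(config.inserts_per_clone_mean)))
                for _ in range(n_ins):
                    spec = pool[int(rng.choice(len(pool), p=weights))]
                    clone_specs.append((spec, draw_trunc(spec)))
                for spec, trunc in clone_specs:
                    gene = gene_by_id[spec.gene_id]
                    truth = realize(spec, lib, clone, trunc)
                    seq, gp, gx, gd = _amplicon_arrays(
                        genome, gene, gene_index[spec.gene_id], truth
                    )
                    truth = dataclasses.replace(truth, amplicon_len=len(seq))
                    paths.inserts.append(truth)
                    amp_seqs.append(seq)
                    amp_gpos.append(gp)
                    amp_gidx.append(gx)
                    amp_gdir.append(gd)
                    # first retained cDNA base (truncation may fall inside a
                    # skipped exon, in which case the junction is the next
                    # kept base)
                    j_gpos = int(gp[len(ATTB1_FLANK)])
                    paths.junctions[(gene.chrom, j_gpos, gene.strand)] = gene.gene_id

            # concatenate this library's amplicons in random order/orientation
            lib_first = len(paths.inserts) - len(amp_seqs)
            order = rng.permutation(len(amp_seqs))
            cat_seq_parts: list[str] = []
            cat_gpos_parts: list[np.ndarray] = []
            cat_gidx_parts: list[np.ndarray] = []
            cat_gdir_parts: list[np.ndarray] = []
            cat_inst_parts: list[np.ndarray] = []
            for inst_id, ai in enumerate(order):
                s, gp, gx, gd = (amp_seqs[ai], amp_gpos[ai], amp_gidx[ai],
                                 amp_gdir[ai])
                if rng.random() < 0.5:
                    s, gp, gx = reverse_complement(s), gp[::-1], gx[::-1]
                    gd = -gd[::-1]
                cat_seq_parts.append(s)
                cat_gpos_parts.append(gp)
                cat_gidx_parts.append(gx)
                cat_gdir_parts.append(gd)
                cat_inst_parts.append(np.full(len(s), inst_id, dtype=np.int32))
            cat_seq = "".join(cat_seq_parts)
            cat_gpos = np.concatenate(cat_gpos_parts)
            cat_gidx = np.concatenate(cat_gidx_parts)
            cat_gdir = np.concatenate(cat_gdir_parts)
            cat_inst = np.concatenate(cat_inst_parts)
            cat_len = len(cat_seq)
            total_mapped[lib] = 0

            bc_pad_gpos = np.full(len(bc), -1, dtype=np.int64)
            bc_pad_inst = np.full(len(bc), -1, dtype=np.int32)
            bc_pad_gdir = np.zeros(len(bc), dtype=np.int8)

            for fi in range(config.fragments_per_library):
                while True:
                    flen = int(
                        rng.normal(config.fragment_length_mean,
                                   config.fragment_length_sd)
                    )
                    flen = min(flen, cat_len)
                    if flen >= max(config.fragment_length_min,
                                   read1_len, read2_len):
                        break
                    print(f"[simulate] {lib}: resampling short fragment "
                          f"({flen} bp)", file=sys.stderr)
                start = int(rng.integers(0, cat_len - flen + 1))
                fs = cat_seq[start : start + flen]
                fg = cat_gpos[start : start + flen]
                fx = cat_gidx[start : start + flen]
                fd = cat_gdir[start : start + flen]
                fn = cat_inst[start : start + flen]
                if rng.random() < 0.5:
                    fs = reverse_complement(fs)
                    fg, fx, fn = fg[::-1], fx[::-1], fn[::-1]
                    fd = -fd[::-1]

                r1_seq = bc + _apply_errors(fs[:read1_len], config.error_rate, rng)
                r1_gpos = np.concatenate([bc_pad_gpos, fg[:read1_len]])
                r1_inst = np.concatenate([bc_pad_inst, fn[:read1_len]])
                r1_gdir = np.concatenate([bc_pad_gdir, fd[:read1_len]])
                r1_gidx = np.concatenate([bc_pad_inst.astype(np.int32),
                                          fx[:read1_len]])
                r2_seq = _apply_errors(
                    reverse_complement(fs[-read2_len:]), config.error_rate, rng
                )
                r2_gpos = fg[-read2_len:][::-1]
                r2_inst = fn[-read2_len:][::-1]
                r2_gdir = -fd[-read2_len:][::-1]
                r2_gidx = fx[-read2_len:][::-1]

                qname = f"{lib}F{fi + 1:06d}"
                a1 = _make_alignment(header, qname, r1_seq, r1_gpos,
                                     r1_inst, r1_gdir, False)
                a2 = _make_alignment(header, qname, r2_seq, r2_gpos,
                                     r2_inst, r2_gdir, True)
                for a, m in ((a1, a2), (a2, a1)):
                    if m.is_unmapped:
                        a.flag |= 0x8
                    else:
                        if m.is_reverse:
                            a.flag |= 0x20
                        a.next_reference_id = m.reference_id
                        a.next_reference_start = m.reference_start
                sam.write(a1)
                sam.write(a2)

                # truth fragment assignment from per-base gene annotation,
                # restricted to each read's chosen aligned run
                overlap: dict[int, int] = {}
                mapped = False
                for gp_arr, gx_arr, in_arr in (
                    (r1_gpos, r1_gidx, r1_inst),
                    (r2_gpos, r2_gidx, r2_inst),
                ):
                    run = _longest_aligned_run(gp_arr, in_arr)
                    if run is None:
                        continue
                    mapped = True
                    gidx = int(gx_arr[run[0]])
                    overlap[gidx] = overlap.get(gidx, 0) + (run[1] - run[0])
                if mapped:
                    total_mapped[lib] += 1
                    if overlap:
                        top = max(overlap.values())
                        winners = [g for g, v in overlap.items() if v == top]
                        if len(winners) == 1:
                            gid = gene_list[winners[0]].gene_id
                            counts[(lib, gid)] = counts.get((lib, gid), 0) + 1

                if config.space == "color":
                    color1.append(
                        ColorRead(qname, "T", encode_colorspace("T" + r1_seq))
                    )
                    color2.append(
                        ColorRead(qname, "G", encode_colorspace("G" + r2_seq))
                    )
                else:
                    q1 = "?" * len(r1_seq)
                    q2 = "?" * len(r2_seq)
                    fq1.write(f"@{qname}/1\n{r1_seq}\n+\n{q1}\n")
                    fq2.write(f"@{qname}/2\n{r2_seq}\n+\n{q2}\n")
    finally:
        fq1.close()
        fq2.close()
        sam.close()

    if config.space == "color":
        write_color_file(str(paths.reads1), color1)
        write_color_file(str(paths.reads2), color2)

    with open(paths.barcodes, "w") as fh:
        for lib, bc in barcodes.items():
            fh.write(f"{lib}\t{bc}\n")
    with open(paths.truth_inserts, "w") as fh:
        fh.write("library_id\tclone_id\tgene_id\ttrunc_tpos\tvariants\t"
                 "skipped_exons\tamplicon_len\n")
        for t in paths.inserts:
            var = ";".join(f"{p}:{r}>{a}" for p, r, a in t.variants)
            sk = ";".join(map(str, t.skipped_exons))
            fh.write(f"{t.library_id}\t{t.clone_id}\t{t.gene_id}\t"
                     f"{t.trunc_tpos}\t{var}\t{sk}\t{t.amplicon_len}\n")
    with open(paths.truth_counts, "w") as fh:
        fh.write("library_id\tgene_id\tfragment_count\n")
        for (lib, gid), n in sorted(counts.items()):
            fh.write(f"{lib}\t{gid}\t{n}\n")
        for lib, n in sorted(total_mapped.items()):
            fh.write(f"{lib}\t__total_mapped__\t{n}\n")
    paths.counts = counts
    paths.total_mapped = total_mapped
    print(f"[simulate] seed={config.seed} libraries={config.n_libraries} "
          f"inserts={len(paths.inserts)}", file=sys.stderr)
    return paths
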