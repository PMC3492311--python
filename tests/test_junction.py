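"""Junction detection, demultiplexing and fusion-coordinate resolution."""

import logging

import pysam
import pytest

from attbdeconv.colorspace import ColorRead, encode_colorspace, reverse_complement
from attbdeconv.junction import (
    FusionSite,
    JunctionHit,
    Read,
    _query_to_ref,
    aggregate_fusion_sites,
    demultiplex,
    detect_attb,
    load_fastq,
    resolve_fusion_coordinate,
)
from attbdeconv.screen_sim import ATTB1_FLANK

HEADER = pysam.AlignmentHeader.from_references(["chr1"], [10_000_000])


def make_aln(qname="r1", pos=0, cigar="75M", seq="A" * 75, reverse=False):
    a = pysam.AlignedSegment(HEADER)
    a.query_name = qname
    a.flag = 16 if reverse else 0
    a.reference_id = 0
    a.reference_start = pos
    a.mapping_quality = 60
    a.cigarstring = cigar
    a.query_sequence = seq
    return a


class TestDemultiplex:
    TABLE = {"libA": "ACGTAC", "libB": "TTTGGG"}

    def test_exact_barcodes_fully_assigned(self):
        reads = [Read("x", "ACGTAC" + "A" * 20), Read("y", "TTTGGG" + "C" * 20)]
        assigned, unassigned = demultiplex(reads, self.TABLE, 0)
        assert [r.read_id for r in assigned["libA"]] == ["x"]
        assert [r.read_id for r in assigned["libB"]] == ["y"]
        assert not unassigned

    def test_one_mismatch_tolerance(self):
        read = Read("x", "ACGTAA" + "G" * 20)
        assigned0, unassigned0 = demultiplex([read], self.TABLE, 0)
        assert unassigned0 == [read]
        assigned1, unassigned1 = demultiplex([read], self.TABLE, 1)
        assert assigned1["libA"] == [read]

    def test_matches_exhaustive_hamming_oracle(self, rng):
        from attbdeconv.screen_sim import default_barcodes

        barcodes = dict(
            (f"l{i}", bc) for i, bc in enumerate(default_barcodes(21, 6))
        )
        for maxmm in (0, 1):
            reads = [
                Read(f"r{i}", "".join(rng.choice("ACGT") for _ in range(30)))
                for i in range(300)
            ]
            assigned, unassigned = demultiplex(reads, barcodes, maxmm)
            got = {}
            for lib, rs in assigned.items():
                for r in rs:
                    got[r.read_id] = lib
            for r in reads:
                dists = {
                    lib: sum(a != b for a, b in zip(r.seq[:6], bc))
                    for lib, bc in barcodes.items()
                }
                dmin = min(dists.values())
                winners = [l for l, d in dists.items() if d == dmin]
                if dmin <= maxmm and len(winners) == 1:
                    assert got.get(r.read_id) == winners[0]
                else:
                    assert r.read_id not in got


class TestDetectAttb:
    CDNA = "ACGGATTACACCAGGTTCAA"

    def test_forward_hit_after_full_flank(self):
        read = Read("r1", ATTB1_FLANK + self.CDNA)
        (hit,) = detect_attb(read)
        assert hit.orientation == "forward"
        assert hit.cdna_offset == len(ATTB1_FLANK)
        assert not hit.partial

    def test_reverse_complemented_read_mirrored_offset(self):
        seq = reverse_complement(ATTB1_FLANK + self.CDNA)
        (hit,) = detect_attb(Read("r1", seq))
        assert hit.orientation == "reverse"
        # first cDNA base sits just left of the reverse-complemented spacer
        assert hit.cdna_offset == len(self.CDNA) - 1
        assert not hit.partial

    def test_truncated_spacer_flags_partial(self):
        read = Read("r1", ATTB1_FLANK[: len(ATTB1_FLANK) - 5])
        (hit,) = detect_attb(read)
        assert hit.partial

    def test_corrupted_spacer_rejected(self):
        flank = ATTB1_FLANK[:-10] + "TTTTTTTTTT"
        assert detect_attb(Read("r1", flank + self.CDNA)) == []

    def test_no_anchor_no_hits(self):
        assert detect_attb(Read("r1", "ACGT" * 20)) == []

    def test_hits_match_simulator_truth(self, small_screen):
        """Resolved junction coordinates are exactly the simulated ones."""
        config, genome, genes, bundle = small_screen
        logging.disable(logging.WARNING)
        try:
            with pysam.AlignmentFile(str(bundle.truth_sam)) as fh:
                by_q = {(a.query_name, a.is_read2): a for a in fh}
            sites = []
            n_hits = 0
            for path, is2 in ((bundle.reads1, False), (bundle.reads2, True)):
                for rd in load_fastq(str(path)):
                    hits = detect_attb(rd)
                    n_hits += len(hits)
                    aln = by_q[(rd.read_id[:-2], is2)]
                    if aln.is_unmapped:
                        continue
                    for h in hits:
                        s = resolve_fusion_coordinate(h, aln, genes)
                        if s is not None:
                            sites.append(s)
        finally:
            logging.disable(logging.NOTSET)
        assert n_hits > 50
        assert sites
        truth = set(bundle.junctions)
        for s in sites:
            assert (s.chrom, s.gpos, s.strand) in truth
            assert bundle.junctions[(s.chrom, s.gpos, s.strand)] == s.gene_id

    def test_color_space_detection_equals_base_space(self, small_screen):
        """Encoding the same reads into colors yields the identical hit set."""
        config, genome, genes, bundle = small_screen
        reads = load_fastq(str(bundle.reads1))[:800]
        for rd in reads:
            base_hits = [
                (h.orientation, h.cdna_offset, h.partial)
                for h in detect_attb(rd)
            ]
            cr = ColorRead(rd.read_id, "T", encode_colorspace("T" + rd.seq))
            color_hits = [
                (h.orientation, h.cdna_offset, h.partial)
                for h in detect_attb(cr, space="color")
            ]
            assert base_hits == color_hits


class TestResolveFusionCoordinate:
    def _hit(self, offset, orientation="forward", read_id="r1"):
        return JunctionHit(read_id, "attB1", orientation, offset, "base")

    def test_soft_clipped_forward(self):
        aln = make_aln(pos=1000, cigar="20S55M")
        site = resolve_fusion_coordinate(self._hit(20), aln, [])
        assert (site.chrom, site.gpos, site.strand) == ("chr1", 1000, "+")

    def test_spliced_alignment_crosses_gap(self):
        aln = make_aln(pos=500, cigar="10S30M200N35M")
        site = resolve_fusion_coordinate(self._hit(45), aln, [])
        # per-base oracle from the alignment itself
        oracle = dict(aln.get_aligned_pairs(matches_only=True))
        assert site.gpos == oracle[45] == 500 + 30 + 200 + 5

    def test_reverse_strand_alignment(self):
        # read offset o maps to SAM query offset L-1-o
        aln = make_aln(pos=2000, cigar="60M15S", reverse=True)
        site = resolve_fusion_coordinate(self._hit(20), aln, [])
        oracle = dict(aln.get_aligned_pairs(matches_only=True))
        assert site.gpos == oracle[75 - 1 - 20]
        assert site.strand == "-"

    def test_first_cdna_base_in_clip_unresolvable(self):
        aln = make_aln(pos=1000, cigar="30S45M")
        assert resolve_fusion_coordinate(self._hit(20), aln, []) is None

    def test_short_cdna_tail_unresolvable(self):
        aln = make_aln(pos=1000, cigar="72M3S")
        assert resolve_fusion_coordinate(self._hit(72), aln, []) is None

    def test_mismatched_read_name_raises(self):
        aln = make_aln(qname="other")
        with pytest.raises(ValueError):
            resolve_fusion_coordinate(self._hit(10), aln, [])

    def test_query_walk_matches_pysam_oracle(self, rng):
        """Arithmetic CIGAR walk vs per-base aligned-pairs enumeration on
        random clipped/spliced/inserted alignments."""
        for _ in range(10_000 // 10):
            parts = []
            if rng.random() < 0.7:
                parts.append((4, rng.randint(1, 20)))
            parts.append((0, rng.randint(1, 30)))
            for _ in range(rng.randint(0, 3)):
                op = rng.choice([1, 2, 3])
                parts.append((op, rng.randint(1, 200 if op == 3 else 5)))
                parts.append((0, rng.randint(1, 30)))
            if rng.random() < 0.7:
                parts.append((4, rng.randint(1, 20)))
            qlen = sum(ln for op, ln in parts if op in (0, 1, 4))
            aln = make_aln(pos=rng.randint(0, 5000),
                           cigar="".join(f"{ln}{'MIDNSHP=X'[op]}" for op, ln in parts),
                           seq="A" * qlen)
            oracle = {}
            for q, r in aln.get_aligned_pairs():
                if q is not None:
                    oracle[q] = r
            for q in range(0, qlen, max(1, qlen // 10)):
                assert _query_to_ref(aln, q) == oracle[q]


class TestAggregate:
    def test_reads_collapse_onto_one_site(self):
        sites = [FusionSite("G1", "chr1", 100, "+")] * 3
        table, summary = aggregate_fusion_sites(sites)
        assert len(table) == 1
        assert table.read_count.iloc[0] == 3
        assert summary.distinct_sites.iloc[0] == 1

    def test_sorted_by_support_then_coordinate(self):
        sites = (
            [FusionSite("G1", "chr1", 200, "+")] * 2
            + [FusionSite("G1", "chr1", 100, "+")] * 5
            + [FusionSite("G2", "chr1", 900, "-")]
        )
        table, summary = aggregate_fusion_sites(sites)
        assert list(table.gpos) == [100, 200, 900]
        assert list(summary.gene_id) == ["G1", "G2"]
        assert summary.distinct_sites.tolist() == [2, 1]

    def test_empty_input(self):
        table, summary = aggregate_fusion_sites([])
        assert table.empty and summary.empty
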