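"""Quantification, pileup VAF, consequence annotation, skips, nomination."""

import random

import numpy as np
import pysam
import pytest

from attbdeconv.quantvar import (
    ExonSkipEvent,
    GeneQuant,
    VariantCall,
    Consequence,
    annotate_substitution,
    call_variants,
    compute_fpkm,
    count_fragments,
    detect_exon_skips,
    nominate_candidates,
    pileup_vaf,
)
from attbdeconv.refmodel import GeneModel, Genome
from conftest import random_dna

HEADER = pysam.AlignmentHeader.from_references(["chr1"], [1_000_000])


def make_aln(qname, pos, cigar, seq=None, flag=0):
    a = pysam.AlignedSegment(HEADER)
    a.query_name = qname
    a.flag = flag
    a.reference_id = 0
    a.reference_start = pos
    a.mapping_quality = 60
    a.cigarstring = cigar
    qlen = sum(ln for op, ln in a.cigartuples if op in (0, 1, 4, 7, 8))
    a.query_sequence = seq if seq is not None else "A" * qlen
    return a


GENE_A = GeneModel("A", "chr1", "+", ((1000, 2000),))
GENE_B = GeneModel("B", "chr1", "+", ((2100, 2500),))


class TestCountFragments:
    def test_pairs_inside_one_gene(self):
        alns = []
        for i in range(10):
            alns.append(make_aln(f"f{i}", 1100, "75M", flag=0x41))
            alns.append(make_aln(f"f{i}", 1500, "35M", flag=0x81))
        counts, total = count_fragments(alns, [GENE_A, GENE_B])
        assert counts == {"A": 10}
        assert total == 10

    def test_maximal_overlap_assignment(self):
        # 60 bases in A, 20 bases in B (via two mates)
        alns = [
            make_aln("f1", 1940, "60M15S", flag=0x41),
            make_aln("f1", 2100, "20M15S", flag=0x81),
        ]
        counts, _ = count_fragments(alns, [GENE_A, GENE_B])
        assert counts == {"A": 1}

    def test_tie_left_unassigned_but_counted_in_total(self):
        alns = [
            make_aln("f1", 1980, "20M", flag=0x41),
            make_aln("f1", 2100, "20M", flag=0x81),
        ]
        counts, total = count_fragments(alns, [GENE_A, GENE_B])
        assert counts == {}
        assert total == 1

    def test_orphan_mate_counts_as_single_end_fragment(self):
        alns = [make_aln("f1", 1100, "75M", flag=0x41)]
        counts, total = count_fragments(alns, [GENE_A])
        assert counts == {"A": 1} and total == 1

    def test_counts_equal_simulator_truth(self, small_screen):
        """CIGAR-walk counting reproduces the generator's per-base truth."""
        config, genome, genes, bundle = small_screen
        with pysam.AlignmentFile(str(bundle.truth_sam)) as fh:
            counts, total = count_fragments(fh, genes)
        truth = {g: n for (lib, g), n in bundle.counts.items()}
        assert counts == truth
        assert total == bundle.total_mapped["lib01"]


class TestComputeFpkm:
    def test_direct_arithmetic(self):
        (q,) = compute_fpkm({"A": 100}, [GENE_A], 10**6)
        assert q.fpkm == pytest.approx(100.0)
        assert q.rank == 1

    def test_zero_count_zero_fpkm(self):
        quants = compute_fpkm({"A": 5}, [GENE_A, GENE_B], 100)
        by_id = {q.gene_id: q for q in quants}
        assert by_id["B"].fpkm == 0
        assert by_id["B"].fragment_count == 0

    def test_conservation_identity(self, rng):
        """sum(fpkm * exon_len * total / 1e9) returns the assigned counts."""
        genes = [
            GeneModel(f"G{i}", "chr1", "+", ((i * 3000, i * 3000 + rng.randint(200, 2000)),))
            for i in range(12)
        ]
        counts = {g.gene_id: rng.randint(0, 500) for g in genes}
        total = sum(counts.values()) + rng.randint(1, 100)
        quants = compute_fpkm(counts, genes, total)
        back = sum(q.fpkm * q.exon_len * total / 1e9 for q in quants)
        assert back == pytest.approx(sum(counts.values()))

    def test_ranks_are_permutation_with_lexicographic_ties(self):
        genes = [GeneModel(n, "chr1", "+", ((0, 1000),)) for n in "ZYX"]
        quants = compute_fpkm({"Z": 5, "Y": 5, "X": 9}, genes, 100)
        assert [q.gene_id for q in quants] == ["X", "Y", "Z"]
        assert [q.rank for q in quants] == [1, 2, 3]

    def test_requires_positive_total(self):
        with pytest.raises(ValueError):
            compute_fpkm({}, [GENE_A], 0)


class TestPileupVaf:
    GENOME = Genome({"chr1": "A" * 1_000_000})

    def _reads(self, n_alt, n_ref, site=1500):
        alns = []
        for i in range(n_alt + n_ref):
            base = "C" if i < n_alt else "A"
            seq = "A" * 30 + base + "A" * 44
            alns.append(make_aln(f"r{i}", site - 30, "75M", seq=seq))
        return alns

    def test_monoclonal_full_vaf(self):
        res = pileup_vaf(self._reads(200, 0), self.GENOME, ("chr1", 1500))
        assert res.vaf == 100.0 and res.depth == 200 and res.alt == "C"

    def test_heterozygous_half_vaf(self):
        res = pileup_vaf(self._reads(100, 100), self.GENOME, ("chr1", 1500))
        assert res.vaf == pytest.approx(50.0)

    def test_zero_depth_is_explicit(self):
        res = pileup_vaf([], self.GENOME, ("chr1", 1500))
        assert not res.covered and res.depth == 0

    def test_binomial_sampling_within_confidence_interval(self):
        r = random.Random(5)
        depth, p = 1000, 0.5
        n_alt = sum(r.random() < p for _ in range(depth))
        res = pileup_vaf(self._reads(n_alt, depth - n_alt), self.GENOME,
                         ("chr1", 1500))
        ci = 1.96 * 100 * (p * (1 - p) / depth) ** 0.5
        assert abs(res.vaf - 100 * p) <= ci * 1.5

    def test_estimator_unbiased_over_replicates(self):
        """Mean pileup VAF over 100 binomial replicates within 1% of truth."""
        rng = np.random.default_rng(7)
        depth, p = 100, 0.5
        vafs = []
        for _ in range(100):
            n_alt = int(rng.binomial(depth, p))
            res = pileup_vaf(self._reads(n_alt, depth - n_alt), self.GENOME,
                             ("chr1", 1500))
            vafs.append(res.vaf)
        assert abs(float(np.mean(vafs)) - 50.0) < 1.0


class TestAnnotateSubstitution:
    def test_lysine_codon_70_missense(self, rng):
        """G>T at coding position 210 in an AAG codon: K70N at codon 70."""
        cds = list(random_dna(rng, 300))
        cds[207:210] = "AAG"
        cds = "".join(cds)
        cons = annotate_substitution(None, 210, "G", "T", cds, pos_is_cds=True)
        assert (cons.kind, cons.codon_index) == ("missense", 70)
        assert str(cons) == "K70N"

    def test_dinucleotide_pair_on_utr_transcript(self, rng):
        """With the CDS starting at transcript position 255, A434T is the
        synonymous G60G and C435A the missense Q61K."""
        utr = random_dna(rng, 254)
        cds = list(random_dna(rng, 240))
        cds[177:183] = "GGACAA"  # codons 60 (GGA) and 61 (CAA)
        tseq = utr + "".join(cds)
        gene = GeneModel("NRASlike", "chr1", "+", ((0, len(tseq)),), 255)
        syn = annotate_substitution(gene, 434, "A", "T", tseq)
        mis = annotate_substitution(gene, 435, "C", "A", tseq)
        assert (syn.kind, syn.codon_index, str(syn)) == ("synonymous", 60, "G60G")
        assert (mis.kind, mis.codon_index, str(mis)) == ("missense", 61, "Q61K")

    def test_stop_gain_is_nonsense(self):
        cds = "ATGTGGAAA"  # M W K
        cons = annotate_substitution(None, 5, "G", "A", cds, pos_is_cds=True)
        assert cons.kind == "nonsense"  # TGG -> TAG

    def test_utr_and_noncoding_positions(self):
        tseq = "ACGTACGTACGT"
        gene = GeneModel("G", "chr1", "+", ((0, 12),), 5)
        assert annotate_substitution(gene, 2, "C", "A", tseq).kind == "utr"
        nc = GeneModel("G", "chr1", "+", ((0, 12),), 0)
        assert annotate_substitution(nc, 2, "C", "A", tseq).kind == "noncoding"

    def test_identity_substitution_rejected(self):
        with pytest.raises(ValueError, match="not a variant"):
            annotate_substitution(None, 1, "A", "A", "AAA", pos_is_cds=True)

    def test_ref_mismatch_names_expected_base(self):
        with pytest.raises(ValueError, match="'C'"):
            annotate_substitution(None, 2, "G", "T", "ACA", pos_is_cds=True)


class TestDetectExonSkips:
    GENE = GeneModel("S", "chr1", "+", ((1000, 1100), (1200, 1300), (1400, 1500)))

    def test_exact_skip_gap_counted(self):
        # N gap from exon1 end (1100) to exon3 start (1400)
        alns = [make_aln(f"r{i}", 1050, "50M300N50M") for i in range(3)]
        (ev,) = detect_exon_skips(alns, self.GENE)
        assert (ev.exon_index, ev.junction_reads) == (2, 3)

    def test_canonical_junction_not_an_event(self):
        alns = [make_aln(f"r{i}", 1050, "50M100N50M") for i in range(5)]
        assert detect_exon_skips(alns, self.GENE) == []

    def test_off_by_one_gap_not_counted(self):
        alns = [make_aln(f"r{i}", 1049, "50M301N50M") for i in range(5)]
        assert detect_exon_skips(alns, self.GENE) == []

    def test_min_reads_threshold(self):
        alns = [make_aln("r0", 1050, "50M300N50M")]
        assert detect_exon_skips(alns, self.GENE, min_reads=2) == []

    def test_minus_strand_transcript_indexing(self):
        gene = GeneModel("S", "chr1", "-", self.GENE.exons)
        alns = [make_aln(f"r{i}", 1050, "50M300N50M") for i in range(2)]
        (ev,) = detect_exon_skips(alns, gene)
        assert ev.exon_index == 2  # middle of three either way

    def test_simulated_skip_insert_recovered(self, small_screen):
        """The pool gene carrying a skipped internal exon shows the event."""
        config, genome, genes, bundle = small_screen
        skip_specs = [
            s for s in config.insert_pool if s.skipped_exons
        ]
        assert skip_specs, "demo pool plants one exon-skip gene"
        gene = next(g for g in genes if g.gene_id == skip_specs[0].gene_id)
        with pysam.AlignmentFile(str(bundle.truth_sam)) as fh:
            events = detect_exon_skips(fh, gene)
        assert [e.exon_index for e in events] == list(skip_specs[0].skipped_exons)


class TestCallVariants:
    def test_planted_driver_variant_called_at_full_vaf(self, small_screen):
        config, genome, genes, bundle = small_screen
        with pysam.AlignmentFile(str(bundle.truth_sam)) as fh:
            calls = call_variants(fh, genome, genes)
        driver = config.driver
        ours = [c for c in calls if c.gene_id == driver.gene_id]
        assert len(ours) == 1
        (c,) = ours
        assert (c.tpos, c.alt) == driver.variants[0]
        assert c.vaf == pytest.approx(100.0)
        assert c.consequence.kind == "missense"
        # nothing called on unmutated background genes at zero error rate
        assert {c.gene_id for c in calls} == {driver.gene_id}


class TestNominate:
    def _quant(self, gene_id, rank, fpkm=1000.0):
        return GeneQuant(gene_id, 10, 1000, fpkm, rank)

    def _variant(self, gene_id, kind="missense"):
        return VariantCall(gene_id, 10, "A", "C", 100, 100, 100.0,
                           Consequence(kind, 4, "K", "N"))

    def test_mutated_top_gene_flagged(self):
        import pandas as pd

        summary = pd.DataFrame(
            {"gene_id": ["DRV"], "distinct_sites": [4], "total_reads": [40]}
        )
        report = nominate_candidates(
            [self._quant("DRV", 1, 9e4), self._quant("HK", 2, 1e4)],
            summary, [self._variant("DRV")], [],
        )
        flagged = report[report.flagged]
        assert list(flagged.gene_id) == ["DRV"]
        assert "nonsynonymous" in flagged.reasons.iloc[0]

    def test_high_fpkm_without_event_not_flagged(self):
        import pandas as pd

        report = nominate_candidates(
            [self._quant("HK", 1, 9e4)], pd.DataFrame(), [], [],
        )
        assert not report.flagged.any()

    def test_synonymous_only_not_flagged(self):
        import pandas as pd

        report = nominate_candidates(
            [self._quant("G", 1)], pd.DataFrame(),
            [self._variant("G", "synonymous")], [],
        )
        assert not report.flagged.any()

    def test_event_without_expression_or_sites_not_flagged(self):
        import pandas as pd

        report = nominate_candidates(
            [self._quant("G", 50)], pd.DataFrame(), [self._variant("G")], [],
            top_k=10, min_sites=3,
        )
        assert not report.flagged.any()

    def test_skip_event_counts_as_deleterious(self):
        import pandas as pd

        report = nominate_candidates(
            [self._quant("SK", 2)], pd.DataFrame(), [],
            [ExonSkipEvent("SK", 16, 12)],
        )
        assert report[report.gene_id == "SK"].flagged.iloc[0]

    def test_empty_inputs_empty_report(self):
        import pandas as pd

        report = nominate_candidates([], pd.DataFrame(), [], [])
        assert report.empty
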