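# Methods

## Color space

SOLiD sequencing reports each adjacent base pair as one of four colors
under the standard di-base code (identical pair → 0; A↔C, G↔T → 1; A↔G,
C↔T → 2; A↔T, C↔G → 3). The code is symmetric and closed under
complementation, so `encode(revcomp(s)) == reverse(encode(s))`; the
junction detector therefore searches one pattern and its reversal instead
of re-encoding a reverse complement. Stored color reads carry the primer
anchor base plus one color per sequenced base (the first color is the
transition from the primer base into the read), which makes decoding exact.
The printed pattern anchors (`T…` forward, `G…` reverse) are display
anchors derived from the sequencing primer, not part of the matched
pattern: matching operates on the 16-color string alone. Anchor matching
defaults to 0 mismatches; a flag exposes Hamming-tolerant matching.

## Junction detection and fusion-coordinate resolution

The attB1 flank is the full forward PCR primer
`GGGGACAACTTTGTACAAAAAAGTTGG AAGCAGTGGTATCAACGCAGAG` (space added at the
anchor/spacer boundary): a 10-base prefix, the 17-mer anchor, and a fixed
22-base spacer that immediately precedes the first cDNA base. A hit is
accepted only if the spacer matches where it lies within the read; hits
whose spacer or first cDNA base runs off the read are flagged partial and
never resolved. Only the attB1 side is anchored by default (attB2 anchoring
is not implemented; the attB2 flank differs from the anchor at two
positions and is never matched exactly).

Resolution projects the first-cDNA-base read offset through the alignment
CIGAR: soft clips and insertions consume query only, deletions and splice
gaps consume reference only, and reverse-strand alignments flip read
coordinates (`q → L−1−q`). The fusion strand is the XOR of hit orientation
and alignment strand. A hit resolves only if the first `min_flank = 5` cDNA
bases are all *aligned* (M operations): this rejects reads whose cDNA tail
is too short to have been mappable and sub-`min_flank` aligned stubs whose
strand is geometrically ambiguous. The value 5 is a design choice (the
shortest tail worth trusting without mapping), not a fitted threshold.

Distinct sites are exact `(chrom, gpos, strand)` groups — the simulator has
no mapping jitter, and distinctness is the quantity of interest (each
distinct 5' UTR endpoint marks an independent full-length transcript).
Gene assignment falls back to the nearest gene within 1 kb for coordinates
just outside annotated exons (5' extensions), else `unassigned`.

## Quantification

Fragments (read pairs; orphan mates count as single-end fragments) are
assigned to the gene with maximal exonic overlap of their aligned bases;
ties and zero-overlap fragments stay unassigned but count toward the
mapped total. FPKM uses the merged exon length of the single-isoform model
as the "kilobase of exon" denominator:

    fpkm = fragment_count × 10^9 / (exon_len × total_mapped_fragments)

which satisfies the conservation identity
`Σ fpkm·exon_len·total/10^9 = Σ assigned counts` on every table. Ranks
break ties lexicographically by gene id. Quantification is per library:
the pipeline demultiplexes first and ranks within each library's amplified
pool, because abundances are only comparable within one pool.

## Variants and exon skips

The internal caller is a naive pileup (primary, non-duplicate alignments;
most frequent non-reference base; VAF in percent). Defaults: depth ≥ 10,
alternate fraction ≥ 0.2 — permissive on purpose, since a clonal screen
yields near-0%/50%/100% fractions and external call sets can be supplied
instead. Consequences use the standard genetic code on the transcript
strand; the affected codon is `ceil((tpos − cds_start + 1)/3)`; stop gains
are labeled nonsense; positions before the coding start (or past the last
complete codon) are `utr`, and transcripts without an annotated coding
start are `noncoding`. Gene models keep only the coding start; the coding
region is taken to run to the transcript 3' end, which is sufficient for
codon arithmetic on screen-recovered variants and is what the BED12 writer
emits as the thick region.

Exon skips are called for internal exons only, from alignments whose `N`
gap joins the flanking exons' boundaries *exactly* (no fuzz — simulated
alignments are jitter-free; real spliced aligners place these boundaries
exactly when the flanking anchors map), with `min_reads = 2`.

Nomination: a gene is flagged iff it has a deleterious event (non-synonymous
variant or exon skip) AND (FPKM rank ≤ `top_k = 10` OR distinct fusion
sites ≥ `min_sites = 3`). Unflagged genes stay in the report as background;
the characteristic negative pattern is a highly expressed, variant-free
housekeeping transcript.

## The simulator

The generator reproduces the screen's design parameters: 21 libraries by
default, ~10 surviving clones per library, Poisson(mean 7, minimum 1)
inserts per clone, ~2 kb inserts, amplicons built as
`attB1_forward_primer + truncated/edited cDNA + revcomp(attB2_reverse_primer)`,
per-library concatenation in random order and orientation, normal(500, 100)
shear lengths floored at 150 bp, 75+35 paired reads, and a 6-bp library
barcode prefixed to read 1 (barcode length/placement and the shear
distribution are unspecified in the original design; these are package
choices). 5' truncation points are uniform over the 5' UTR, modeling
variable first-strand extension past the start codon. Substitution
sequencing errors are supported (default 0); indel errors, PCR duplicates
and amplification bias are not modeled.

Each read is emitted with its ground-truth alignment: the longest
contiguous run of insert-derived bases from a single amplicon copy is
aligned (M runs split by `N` across introns; reverse-strand encoding when
the run's per-base orientation is minus), and everything else — barcode,
vector flanks, adjacent-amplicon carry-over — is soft-clipped. Truth
per-gene fragment counts come from the generator's own per-base gene
annotation restricted to those aligned runs, an independent route from the
SAM-walking counter they validate. A read touching two amplicons keeps only
its longest run, exactly as a real aligner keeps one primary locus.

A *driver* insert can be planted into every clone of designated libraries,
cycling deterministically through a fixed set of truncation points. This
models the selection step — every surviving clone carries the transforming
cDNA, and independent transcripts differ in 5' UTR length — and gives the
end-to-end tests an exact expectation for the distinct-site count.

What passing these tests does **not** show about real data: mapping error,
soft-clip jitter at junctions, PCR chimeras and duplicate structure,
quality-dependent errors, and overlapping gene annotations are all absent
from the generator, so real screens need the tolerant-matching and
site-merging (`--merge-within`-style) options rather than the exact
defaults used here.

## Scale and determinism

Bundled study conditions are desk-scale: the end-to-end checks use a
3-library screen (10 clones/library, Poisson-7 inserts, 12,000 fragments
per library, one planted driver with k = 4 truncation points), which gives
every junction ≳10 expected resolvable spanning reads and runs in well
under a minute; the monoclonal VAF measurement uses one clone, one insert
species and ≥200 reads over the site. The originally reported screen-scale
figures (e.g. an FPKM of 61,516 for the top driver and 12 distinct fusion
sequences in one library) require the original read data and are replaced
by these property-equivalent checks at simulation scale. Every stochastic
stage consumes an explicit seed; reruns of the same configuration are
byte-identical, and the pipeline manifest records thresholds and input
checksums (no timestamps).

## Known limitations

- One transcript per gene model; no isoform collapse or multi-mapping
  rescue.
- No chimeric-alignment rescue or split-read fusion discovery between two
  genes; alignments are consumed, not produced.
- attB2-side junction collection is not implemented.
- The naive caller handles substitutions only; external VCFs are the route
  for anything else.
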