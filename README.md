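# attbdeconv

Deconvolution of pooled, attB-flanked cDNA phenotype screens from
next-generation sequencing reads.

## The problem

Gain-of-function screens transduce full-length cDNA libraries into an
IL3-dependent reporter line (Ba/F3) and select clones that proliferate
without cytokine. Each surviving clone carries several retrovirally
integrated cDNA inserts, every one flanked by Gateway attB recombination
sequence; pooled clones from many libraries are PCR-amplified,
concatenated, sheared and sequenced with per-library barcodes
(asymmetric 75+35 bp pairs, originally on a SOLiD instrument that reports
reads in two-base *color space*). The informatic task this package solves
is the read-out: which transcripts did each library's surviving clones
carry, where exactly does each integrated insert begin, and which of the
recovered transcripts is the driver?

The key observations it operationalizes:

- A read crossing the vector/insert boundary carries a fixed attB1 anchor
  `TTGTACAAAAAAGTTGG` (color space: forward `0113110000021010`, reverse
  `0101200000113110` — reversing a sequence's complement reverses its color
  string), followed by a fixed 22-base spacer and then the first cDNA base.
- Projecting that first cDNA base through the read's alignment — honoring
  soft clips, reverse-strand mappings and `N` splice gaps — gives the
  genomic *fusion coordinate*. Distinct coordinates within one gene mark
  independent full-length transcripts that differ in 5' UTR length.
- Driver transcripts dominate their library's amplified pool. Expression is
  ranked by FPKM: `fpkm = fragments x 10^9 / (merged exon length x total
  mapped fragments)`. A gene is nominated when it carries a deleterious
  event (non-synonymous substitution, by pileup VAF and codon arithmetic,
  or an internal exon skip seen as an exact splice gap) *and* is either
  near the top of the FPKM ranking or supported by several independent
  fusion sites.

A bundled simulator generates the whole screen — clones, Poisson-distributed
inserts, 5' truncations, variants, exon skips, concatenation, shearing,
barcoded 75+35 pairs in base or color space — together with ground-truth
alignments and per-gene counts, so every stage is testable exactly.

## Worked example

`examples/simulate_and_deconvolute.py` simulates a one-library screen with
a planted driver (four distinct 5' truncation points and a missense
substitution) and runs the full pipeline:

```
-- driver fusion sites (distinct 5' UTR truncation points) --
gene_id  distinct_sites  total_reads library_id
GENE001               4           37      lib01

-- top of the FPKM table --
gene_id  fragment_count  exon_len         fpkm  rank library_id
GENE001             929      1061 146077.58870     1      lib01
GENE020             287       513  93335.70087     2      lib01

-- variant calls --
library_id gene_id  tpos ref alt  depth  alt_count  vaf consequence_kind consequence
     lib01 GENE001   257   C   A    103        103  100         missense         H1N

-- flagged driver candidates --
gene_id         fpkm  fpkm_rank  distinct_fusion_sites  n_nonsyn_variants  n_exon_skips  flagged
GENE001 146077.58870          1                      4                  1             0     True
GENE003  48022.43608          9                      4                  0             1     True
```

The planted gene ranks first by FPKM, shows one fusion site per planted
truncation point, carries its substitution at 100% variant allele fraction
(every integrated copy is mutant), and is flagged; a second gene planted
with an internal-exon skip is flagged through the splice-gap route, while
highly expressed but unmutated background genes are not. The other
examples show the color-space patterns, the coverage-design arithmetic
(2,940,000 bp of pooled cDNA at ~3,401-fold for 10^10 sequenced bases)
and codon-level annotation (`K70N`, `G60G`/`Q61K`).

The same stages are available from the shell:

```sh
attb-screen simulate --out sim --seed 1
attb-screen plan-coverage --specimens 21 --clones-per-specimen 10 \
    --inserts-per-clone 7 --mean-insert-bp 2000 --sequenced-bp 1e10
attb-screen run-all --config pipeline.json
```

## Layout

- `src/attbdeconv/colorspace.py` — SOLiD di-base encoding/decoding, pattern search
- `src/attbdeconv/refmodel.py` — gene models (BED12), FASTA access, transcript↔genome coordinates
- `src/attbdeconv/screen_sim.py` — screen simulator and coverage planner
- `src/attbdeconv/junction.py` — demultiplexing, attB detection, fusion-coordinate resolution
- `src/attbdeconv/quantvar.py` — fragment counting, FPKM, pileup/VAF, consequences, exon skips, nomination
- `src/attbdeconv/pipeline.py`, `cli.py` — orchestration and the `attb-screen` command
- `docs/methods.md` — model assumptions, parameter defaults and limitations
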