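"""Codon-level consequences of substitutions in recovered transcripts.

Two classic patterns: a missense change given coding-sequence coordinates,
and a dinucleotide substitution given transcript coordinates on a
transcript with a 254-base 5' UTR (coding sequence starts at position
255) — one base is silent, its neighbor changes the amino acid.
"""

import random

from attbdeconv import GeneModel, annotate_substitution

rng = random.Random(0)

# K70N: codon 70 (AAG, lysine) hit at its third base, CDS position 210
cds = list("".join(rng.choice("ACGT") for _ in range(300)))
cds[207:210] = "AAG"
cons = annotate_substitution(None, 210, "G", "T", "".join(cds), pos_is_cds=True)
print(f"G210T in CDS        -> {cons} ({cons.kind}, codon {cons.codon_index})")

# G60G / Q61K: transcript coordinates with a 254-nt 5' UTR
utr = "".join(rng.choice("ACGT") for _ in range(254))
body = list("".join(rng.choice("ACGT") for _ in range(240)))
body[177:183] = "GGACAA"  # codon 60 = GGA, codon 61 = CAA
tseq = utr + "".join(body)
gene = GeneModel("NRAS-like", "chr1", "+", ((0, len(tseq)),), cds_start_tpos=255)
for tpos, ref, alt in [(434, "A", "T"), (435, "C", "A")]:
    cons = annotate_substitution(gene, tpos, ref, alt, tseq)
    print(f"{ref}{tpos}{alt} in transcript -> {cons} ({cons.kind})")
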