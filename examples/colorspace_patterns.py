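"""Encode the Gateway attB junction anchor into SOLiD color space.

The detector searches reads for the attB1 anchor in color space; the
reverse-complement search needs no second encoding because reversing a
DNA sequence's complement simply reverses its color string.
"""

from attbdeconv import (
    ATTB_ANCHOR,
    attb_color_patterns,
    decode_colorspace,
    encode_colorspace,
)

print(f"anchor sequence : {ATTB_ANCHOR}")
print(f"anchored colors : {encode_colorspace(ATTB_ANCHOR, with_anchor=True)}")
fwd, rev = attb_color_patterns(ATTB_ANCHOR)
print(f"forward pattern : {fwd}")
print(f"reverse pattern : {rev}   (= forward reversed: {fwd[::-1] == rev})")
print(f"decoded back    : {decode_colorspace(ATTB_ANCHOR[0], fwd)}")
# The two patterns are what a color-space read shows when it crosses the
# vector/cDNA boundary in either orientation.
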