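"""SOLiD two-base (color-space) encoding, decoding and pattern search.

SOLiD sequencers interrogate overlapping base pairs: each adjacent pair of
bases is reported as one of four colors.  The di-base code is closed under
complementation, which gives color space its key property: the color string
of the reverse complement of a sequence is the reversal of the color string
of the sequence itself.  The junction detector exploits this to search for
the Gateway attB anchor in either orientation with a single pattern and its
reversal.

A read is stored as a known primer-derived anchor base plus one color per
sequenced base; decoding from the anchor reproduces the base sequence.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Iterator

__all__ = [
    "ColorRead",
    "ATTB_ANCHOR",
    "ATTB_FORWARD_PATTERN",
    "ATTB_REVERSE_PATTERN",
    "encode_colorspace",
    "decode_colorspace",
    "attb_color_patterns",
    "match_colors",
    "read_color_file",
    "write_color_file",
]

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# Standard SOLiD di-base code: identical pair -> 0; A<->C and G<->T -> 1;
# A<->G and C<->T -> 2; A<->T and C<->G -> 3.  Symmetric and closed under
# complementation; each row is a permutation of {0,1,2,3}.
TRANSITION_CODE: dict[tuple[str, str], int] = {}
for _i, _a in enumerate(_BASES):
    for _j, _b in enumerate(_BASES):
        TRANSITION_CODE[(_a, _b)] = _i ^ _j

_DECODE: dict[tuple[str, int], str] = {
    (a, c): b for (a, b), c in TRANSITION_CODE.items()
}

#: Gateway attB 17-mer anchor shared by the attB1 and (up to 2 mismatches)
#: attB2 flanks; the sequence the junction detector searches for.
ATTB_ANCHOR = "TTGTACAAAAAAGTTGG"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_colorspace(seq: str, with_anchor: bool = False) -> str:
    """Encode a DNA string into SOLiD colors.

    Returns ``len(seq) - 1`` color digits, one per adjacent base pair.  With
    ``with_anchor`` the first base of ``seq`` is prepended, giving the
    display form used for printed patterns (e.g. ``T0113110000021010``).

    Raises ``ValueError`` on ambiguous bases, naming the offending position.
    """
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2 to encode")
    s = seq.upper()
    for pos, base in enumerate(s):
        if base not in _BASES:
            raise ValueError(
                f"ambiguous or invalid base {base!r} at position {pos}"
            )
    colors = "".join(
        str(TRANSITION_CODE[(s[i], s[i + 1])]) for i in range(len(s) - 1)
    )
    return (s[0] + colors) if with_anchor else colors


def decode_colorspace(anchor: str, colors: str) -> str:
    """Decode colors back to bases given the preceding anchor base.

    Inverse of :func:`encode_colorspace`:
    ``decode(s[0], encode(s)) == s`` for every valid DNA string ``s``.
    """
    a = anchor.upper()
    if a not in _BASES:
        raise ValueError(f"invalid anchor base {anchor!r}")
    if not colors:
        raise ValueError("empty color string")
    out = [a]
    prev = a
    for pos, c in enumerate(colors):
        if c not in "0123":
            raise ValueError(f"invalid color digit {c!r} at position {pos}")
        prev = _DECODE[(prev, int(c))]
        out.append(prev)
    return "".join(out)


def attb_color_patterns(anchor_seq: str = ATTB_ANCHOR) -> tuple[str, str]:
    """Forward and reverse color patterns for an anchor sequence.

    forward = encode(anchor_seq); reverse = encode(revcomp(anchor_seq)).
    By the complement-closure of the di-base code the reverse pattern is the
    character reversal of the forward one.
    """
    forward = encode_colorspace(anchor_seq)
    reverse = encode_colorspace(reverse_complement(anchor_seq))
    return forward, reverse


# Printed-pattern constants for the default anchor.
ATTB_FORWARD_PATTERN, ATTB_REVERSE_PATTERN = attb_color_patterns()


@dataclasses.dataclass(frozen=True)
class ColorRead:
    """A SOLiD read: primer anchor base plus one color per sequenced base."""

    read_id: str
    anchor: str
    colors: str

    def __post_init__(self) -> None:
        if self.anchor.upper() not in _BASES:
            raise ValueError(f"anchor must be A/C/G/T, got {self.anchor!r}")
        if not set(self.colors) <= set("0123"):
            raise ValueError(f"colors of {self.read_id} contain non-digits")

    def decode(self) -> str:
        """Base-space sequence of the read (anchor base dropped)."""
        return decode_colorspace(self.anchor, self.colors)[1:]


def _hamming_le(a: str, b: str, limit: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > limit:
                return False
    return True


def match_colors(
    read: ColorRead | str,
    pattern: str,
    max_mismatches: int = 0,
    *,
    search_reverse: bool = True,
) -> list[tuple[int, str]]:
    """Find a color pattern in a read's color string, both orientations.

    The reverse-orientation pattern is the character reversal of ``pattern``
    (color-space reverse-complement identity).  Returns ``(offset,
    orientation)`` pairs sorted by offset; overlapping matches are all
    reported.  A pattern longer than the color string yields no matches.
    """
    if not pattern:
        raise ValueError("empty pattern")
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    colors = read.colors if isinstance(read, ColorRead) else read
    hits: list[tuple[int, str]] = []
    rev = pattern[::-1]
    palindrome = rev == pattern
    n, m = len(colors), len(pattern)
    for off in range(n - m + 1):
        window = colors[off : off + m]
        if _hamming_le(window, pattern, max_mismatches):
            hits.append((off, "forward"))
        if (
            search_reverse
            and not palindrome
            and _hamming_le(window, rev, max_mismatches)
        ):
            hits.append((off, "reverse"))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def read_color_file(path: str) -> Iterator[ColorRead]:
    """Parse color reads from two-column TSV or csfasta-style records.

    TSV lines are ``read_id<TAB>anchor+colors``; csfasta records are a
    ``>id`` header followed by an anchor+colors line.  Comment lines
    beginning with ``#`` are skipped.
    """
    with open(path) as fh:
        pending_id: str | None = None
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                pending_id = line[1:].split()[0]
                continue
            if pending_id is not None:
                rid, payload = pending_id, line
                pending_id = None
            elif "\t" in line:
                rid, payload = line.split("\t", 1)
                payload = payload.strip()
            else:
                raise ValueError(f"{path}:{lineno}: unrecognized record")
            yield ColorRead(rid, payload[0], payload[1:])


def write_color_file(path: str, reads: Iterable[ColorRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.read_id}\t{r.anchor}{r.colors}\n")
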