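"""Bit-parallel banded edit-distance rows (Myers-style delta vectors).

One :class:`BitRow` holds a full column of the unit-cost edit-distance matrix
between a fixed pattern block P (vertical axis, length m) and a growing text
string (horizontal axis, length j), encoded as two delta bitvectors VP/VN
with ``D[i][j] - D[i-1][j] in {+1, 0, -1}``.  All m cells are updated
simultaneously per consumed text character.

Because every cell satisfies ``D[i][j] >= |i - j|``, cells outside the
diagonal band of half-width k automatically carry values greater than k, so
thresholding the full row at k is exactly the banded computation: no explicit
band bookkeeping is needed.

Python integers serve as arbitrary-width machine words, so pattern blocks of
any read length fit in a single "word".
"""

from __future__ import annotations

import numpy as np

_SIGMA = 6


def pattern_eq_masks(pattern_codes) -> list[int]:
    """Per-character match bitmasks; bit i set iff pattern[i] == c.

    Only A/C/G/T (codes 1-4) ever match; the ambiguity placeholder X and the
    sentinel have empty masks, so X in either sequence always mismatches.
    """
    peq = [0] * _SIGMA
    for i, c in enumerate(pattern_codes):
        c = int(c)
        if 1 <= c <= 4:
            peq[c] |= 1 << i
    return peq


class BitRow:
    """Immutable column state of the DP between a pattern block and text."""

    __slots__ = ("peq", "m", "mask", "vp", "vn", "j", "last")

    def __init__(self, peq: list[int], m: int, mask: int, vp: int, vn: int,
                 j: int, last: int) -> None:
        self.peq = peq
        self.m = m
        self.mask = mask
        self.vp = vp
        self.vn = vn
        self.j = j          # text characters consumed so far
        self.last = last    # D[m][j], the final-cell score

    # -- constructors ------------------------------------------------------

    @classmethod
    def fresh(cls, pattern_codes) -> "BitRow":
        """Column 0: D[i][0] = i (all vertical deltas +1)."""
        m = len(pattern_codes)
        mask = (1 << m) - 1
        return cls(pattern_eq_masks(pattern_codes), m, mask, mask, 0, 0, m)

    @classmethod
    def after_exact(cls, pattern_codes, j: int) -> "BitRow":
        """Column j when the first j text chars matched pattern[:j] exactly.

        Then D[i][j] = |i - j|: deltas are -1 for rows 1..j and +1 above.
        """
        m = len(pattern_codes)
        if not 0 <= j <= m:
            raise ValueError("exact prefix longer than the pattern block")
        mask = (1 << m) - 1
        vn = (1 << j) - 1
        return cls(pattern_eq_masks(pattern_codes), m, mask, mask ^ vn, vn,
                   j, m - j)

    # -- the core update ---------------------------------------------------

    def advance(self, c: int) -> "BitRow":
        """Consume one text character; returns the next column state."""
        eq = self.peq[c]
        vp, vn, mask = self.vp, self.vn, self.mask
        xv = eq | vn
        xh = (((eq & vp) + vp) ^ vp) | eq
        ph = vn | (~(xh | vp) & mask)
        mh = vp & xh
        last = self.last
        hibit = 1 << (self.m - 1)
        if ph & hibit:
            last += 1
        elif mh & hibit:
            last -= 1
        ph = ((ph << 1) | 1) & mask
        mh = (mh << 1) & mask
        nvp = mh | (~(xv | ph) & mask)
        nvn = ph & xv
        return BitRow(self.peq, self.m, mask, nvp, nvn, self.j + 1, last)

    # -- cell extraction ---------------------------------------------------

    def values(self) -> np.ndarray:
        """All cell values D[0..m][j] of the current column."""
        nbytes = (self.m + 7) // 8
        vp = np.unpackbits(
            np.frombuffer(self.vp.to_bytes(nbytes, "little"), dtype=np.uint8),
            bitorder="little", count=self.m).astype(np.int64)
        vn = np.unpackbits(
            np.frombuffer(self.vn.to_bytes(nbytes, "little"), dtype=np.uint8),
            bitorder="little", count=self.m).astype(np.int64)
        out = np.empty(self.m + 1, dtype=np.int64)
        out[0] = self.j
        np.cumsum(vp - vn, out=out[1:])
        out[1:] += self.j
        return out

    def minimum(self) -> int:
        """Smallest cell of the column: a lower bound on any completion."""
        if self.m == 0:
            return self.j
        return int(self.values().min())


def band_row_update(row: BitRow, c: int) -> BitRow:
    """Advance a banded DP row by one text character (bit-parallel)."""
    return row.advance(c)
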