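"""Bidirectional FM-index over a concatenated reference.

The index stores the Burrows-Wheeler transforms of the sanitized text and of
its reverse, plain per-character prefix-count (occ) arrays giving O(1) rank,
and a subsampled suffix array (default every 4th text position, matching the
tool's default sampling density).  A :class:`BidirectionalRange` keeps the
suffix-array interval of a partial match synchronized between both BWTs so the
match can be extended by one character on either side in O(sigma).

Multi-record FASTA input is concatenated with a single terminal sentinel.
Matches that would span a record boundary are not prevented during search;
they are discarded when located (see :meth:`FmIndex.resolve_interval`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .alphabet import ALPHABET, EXTENDABLE, SENTINEL, decode, encode

SIGMA = len(ALPHABET)
DEFAULT_SA_SAMPLING = 4


@dataclass(frozen=True)
class RecordInfo:
    """One FASTA record inside the concatenated text."""

    name: str
    start: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class BidirectionalRange:
    """Synchronized half-open SA interval pair; the unit of search state.

    ``fwd`` indexes the suffix array of the text, ``rev`` the suffix array of
    the reversed text; both intervals always have equal width.
    """

    fwd_begin: int
    fwd_end: int
    rev_begin: int
    rev_end: int

    def __post_init__(self) -> None:
        if self.fwd_end - self.fwd_begin != self.rev_end - self.rev_begin:
            raise ValueError("bidirectional intervals out of sync")
        if self.fwd_end < self.fwd_begin:
            raise ValueError("negative-width range")

    @property
    def width(self) -> int:
        return self.fwd_end - self.fwd_begin

    @property
    def empty(self) -> bool:
        return self.width == 0


def suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n), numpy-vectorized).

    Any correct sorter would do; tests cross-check against a naive
    rotation sort.  Requires a unique smallest sentinel at the end.
    """
    n = len(codes)
    rank = codes.astype(np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r_ord, k_ord = rank[order], key2[order]
        bump = np.empty(n, dtype=np.int64)
        bump[0] = 0
        if n > 1:
            bump[1:] = (r_ord[1:] != r_ord[:-1]) | (k_ord[1:] != k_ord[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(bump)
        rank = new_rank
        if rank[order[-1]] == n - 1:
            break
        k *= 2
    sa = np.empty(n, dtype=np.int64)
    sa[rank] = np.arange(n)
    return sa


def _bwt_from_sa(codes: np.ndarray, sa: np.ndarray) -> np.ndarray:
    return codes[(sa - 1) % len(codes)]


def _occ_table(bwt: np.ndarray) -> np.ndarray:
    """occ[c, i] = number of occurrences of c in bwt[:i] (block size 1)."""
    n = len(bwt)
    occ = np.zeros((SIGMA, n + 1), dtype=np.int64)
    for c in range(SIGMA):
        occ[c, 1:] = np.cumsum(bwt == c)
    return occ


class FmIndex:
    """Bidirectional FM-index with a subsampled suffix array."""

    FORMAT_VERSION = 1

    def __init__(
        self,
        codes: np.ndarray,
        records: Sequence[RecordInfo],
        sa_sampling: int = DEFAULT_SA_SAMPLING,
        _sa: np.ndarray | None = None,
        _sa_rev: np.ndarray | None = None,
    ) -> None:
        if sa_sampling < 1:
            raise ValueError(f"sa_sampling must be >= 1, got {sa_sampling}")
        if len(codes) < 2 or codes[-1] != SENTINEL:
            raise ValueError("text must end in the sentinel and be non-empty")
        if np.count_nonzero(codes == SENTINEL) != 1:
            raise ValueError("exactly one sentinel expected")
        self.codes = codes
        self.records = list(records)
        self.sa_sampling = int(sa_sampling)
        self.n = len(codes)

        sa = suffix_array(codes) if _sa is None else _sa
        rev_codes = np.concatenate([codes[:-1][::-1], codes[-1:]])
        sa_rev = suffix_array(rev_codes) if _sa_rev is None else _sa_rev

        self.bwt_f = _bwt_from_sa(codes, sa)
        self.bwt_r = _bwt_from_sa(rev_codes, sa_rev)
        self.occ_f = _occ_table(self.bwt_f)
        self.occ_r = _occ_table(self.bwt_r)
        counts = np.bincount(codes, minlength=SIGMA)
        self.C = np.zeros(SIGMA + 1, dtype=np.int64)
        self.C[1:] = np.cumsum(counts)

        # sampled SA: mark rows whose SA value is a multiple of the sampling
        mark = (sa % self.sa_sampling) == 0
        self._sa_mark = mark
        self._sa_vals = sa[mark]
        self._mark_rank = np.concatenate([[0], np.cumsum(mark)])

    # -- construction -----------------------------------------------------

    @classmethod
    def build(
        cls,
        reference: Iterable[tuple[str, str]] | str,
        sa_sampling: int = DEFAULT_SA_SAMPLING,
    ) -> "FmIndex":
        """Build from FASTA content (text) or an iterable of (name, seq)."""
        if isinstance(reference, str):
            reference = _parse_fasta_text(reference)
        pieces: list[np.ndarray] = []
        records: list[RecordInfo] = []
        offset = 0
        for name, seq in reference:
            enc = encode(seq)
            if len(enc) == 0:
                continue
            records.append(RecordInfo(name, offset, len(enc)))
            pieces.append(enc)
            offset += len(enc)
        if offset == 0:
            raise ValueError("reference is empty after sanitization")
        pieces.append(np.array([SENTINEL], dtype=np.uint8))
        return cls(np.concatenate(pieces), records, sa_sampling)

    # -- queries -----------------------------------------------------------

    def full_range(self) -> BidirectionalRange:
        """Range of the empty pattern: every suffix of both texts."""
        return BidirectionalRange(0, self.n, 0, self.n)

    def _extend(self, rng: BidirectionalRange, c: int, occ: np.ndarray,
                primary: tuple[int, int], secondary: tuple[int, int]
                ) -> tuple[tuple[int, int], tuple[int, int]]:
        b, e = primary
        cnt = occ[:, e] - occ[:, b]
        nb = self.C[c] + occ[c, b]
        ne = nb + cnt[c]
        sb = secondary[0] + int(cnt[:c].sum())
        return (int(nb), int(ne)), (sb, sb + int(cnt[c]))

    def extend_left(self, rng: BidirectionalRange, c: int | str) -> BidirectionalRange:
        """Occurrences of cM given the range of M (backward step on T)."""
        c = _as_code(c)
        (fb, fe), (rb, re_) = self._extend(
            rng, c, self.occ_f, (rng.fwd_begin, rng.fwd_end), (rng.rev_begin, rng.rev_end)
        )
        return BidirectionalRange(fb, fe, rb, re_)

    def extend_right(self, rng: BidirectionalRange, c: int | str) -> BidirectionalRange:
        """Occurrences of Mc given the range of M (backward step on rev(T))."""
        c = _as_code(c)
        (rb, re_), (fb, fe) = self._extend(
            rng, c, self.occ_r, (rng.rev_begin, rng.rev_end), (rng.fwd_begin, rng.fwd_end)
        )
        return BidirectionalRange(fb, fe, rb, re_)

    def locate(self, rng: BidirectionalRange) -> list[int]:
        """Start positions in T of all suffixes in the forward interval.

        LF-walks from each row to the nearest sampled suffix-array entry.
        """
        out = []
        for row in range(rng.fwd_begin, rng.fwd_end):
            steps = 0
            i = row
            while not self._sa_mark[i]:
                c = self.bwt_f[i]
                i = int(self.C[c] + self.occ_f[c, i])
                steps += 1
            out.append(int(self._sa_vals[self._mark_rank[i]]) + steps)
        return out

    def count_exact(self, pattern: str) -> int:
        """Exact occurrence count of pattern in T (the workload estimate)."""
        if any(ch not in "ACGT" for ch in pattern.upper()):
            return 0
        rng = self.full_range()
        for ch in reversed(pattern.upper()):
            rng = self.extend_left(rng, ch)
            if rng.empty:
                return 0
        return rng.width

    def match_range(self, pattern: str) -> BidirectionalRange:
        rng = self.full_range()
        for ch in reversed(pattern.upper()):
            rng = self.extend_left(rng, ch)
        return rng

    # -- coordinate helpers -------------------------------------------------

    def resolve_interval(self, start: int, end: int) -> RecordInfo | None:
        """Record containing [start, end), or None if the interval crosses a
        record boundary (such occurrences are discarded)."""
        for rec in self.records:
            if rec.start <= start and end <= rec.end:
                return rec
        return None

    def text_slice(self, start: int, end: int) -> np.ndarray:
        return self.codes[max(start, 0): min(end, self.n - 1)]

    @property
    def text(self) -> str:
        """The sanitized concatenated text without the sentinel."""
        return decode(self.codes[:-1])

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        return (
            isinstance(other, FmIndex)
            and np.array_equal(self.codes, other.codes)
            and self.sa_sampling == other.sa_sampling
            and self.records == other.records
        )


def _as_code(c: int | str) -> int:
    if isinstance(c, str):
        code = int(encode(c)[0])
    else:
        code = int(c)
    if code == SENTINEL:
        raise ValueError("cannot extend by the sentinel")
    if code not in EXTENDABLE:
        raise ValueError(f"invalid character code {code}")
    return code


def _parse_fasta_text(text: str) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    name: str | None = None
    chunks: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                records.append((name, "".join(chunks)))
            name = line[1:].split()[0]
            chunks = []
        elif name is not None:
            chunks.append(line)
    if name is not None:
        records.append((name, "".join(chunks)))
    return records


def build_index(reference, sa_sampling: int = DEFAULT_SA_SAMPLING) -> FmIndex:
    """Build the bidirectional FM-index for a reference (FASTA text or
    iterable of ``(name, sequence)`` pairs)."""
    return FmIndex.build(reference, sa_sampling)
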