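"""Read-level orchestration: strands, pairing, SAM record construction.

Single-end mapping aligns the read and its reverse complement and reports
one primary record (smallest distance, ties broken by leftmost reference
position, then forward strand) plus secondary records for the remaining
co-optimal or sub-optimal occurrences.  Paired-end mapping enumerates
convergently oriented combinations of the two mates' occurrence sets whose
outer fragment length lies within six standard deviations of the inferred
mean, and keeps every pair minimizing d1 + d2; when no such proper pair
exists the mates fall back to independent single-end mapping.

MAPQ is a documented convention, not a probability: 60 for a unique best
occurrence, 3 when 2-9 co-optimal occurrences exist, 0 for 10 or more.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .alphabet import encode, reverse_complement
from .index import FmIndex
from .matching import (Occurrence, align_global, all_best_match,
                       approximate_match)
from .schemes import MAX_K

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80
FLAG_SECONDARY = 0x100

DEFAULT_FRAGMENT_MODEL = (500.0, 100.0)  # documented fallback (mean, sd)


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read; ``mate`` is 0 (unpaired), 1 or 2."""

    name: str
    sequence: str
    qualities: str | None = None
    mate: int = 0

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"{self.name}: quality/sequence length mismatch")


@dataclass(frozen=True)
class FragmentModel:
    """Fragment-size model; proper pairs must fall in mean +/- 6 sd."""

    mean: float
    sd: float
    n_observations: int = 0
    fallback: bool = False

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("negative fragment-size standard deviation")

    @property
    def low(self) -> float:
        return self.mean - 6.0 * self.sd

    @property
    def high(self) -> float:
        return self.mean + 6.0 * self.sd

    def accepts(self, fragment_length: int) -> bool:
        return self.low <= fragment_length <= self.high


@dataclass
class SamRecord:
    """One SAM alignment line (POS is 1-based; 0 means unavailable)."""

    qname: str
    flag: int
    rname: str = "*"
    pos: int = 0
    mapq: int = 0
    cigar: str = "*"
    rnext: str = "*"
    pnext: int = 0
    tlen: int = 0
    seq: str = "*"
    qual: str = "*"
    tags: dict = field(default_factory=dict)

    @property
    def is_mapped(self) -> bool:
        return not self.flag & FLAG_UNMAPPED


def resolve_error_budget(rate_or_k: float | int, read_length: int) -> int:
    """Turn a maximum error rate (or explicit k) into the integer budget.

    A rate r maps to ``floor(r * read_length)``, capped at the supported
    ceiling of 13 errors; an explicit k beyond the ceiling is an error.
    """
    if isinstance(rate_or_k, (int, np.integer)) and not isinstance(rate_or_k, bool):
        k = int(rate_or_k)
        if not 0 <= k <= MAX_K:
            raise ValueError(f"explicit error budget {k} outside 0..{MAX_K}")
        return k
    rate = float(rate_or_k)
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"error rate must be in [0, 1), got {rate}")
    return min(int(math.floor(rate * read_length)), MAX_K)


def _mapq(n_best: int) -> int:
    if n_best <= 1:
        return 60
    if n_best <= 9:
        return 3
    return 0


@dataclass(frozen=True)
class _Hit:
    """An oriented occurrence with its SAM-ready alignment."""

    occ: Occurrence
    rname: str
    local_start: int  # 0-based within the record
    cigar: str


def _collect_hits(read_seq: str, k: int, mode: str, index: FmIndex,
                  schemes, **options) -> tuple[list[Occurrence], int | None]:
    fwd, rev = read_seq, reverse_complement(read_seq)
    if mode == "all-best":
        occ_f, st_f = all_best_match(fwd, k, index, schemes, **options)
        occ_r, st_r = all_best_match(rev, k, index, schemes, **options)
        strata = [s for s in (st_f, st_r) if s is not None]
        if not strata:
            return [], None
        stratum = min(strata)
        occs = ([o for o in occ_f if o.distance == stratum]
                + [Occurrence(o.start, o.end, o.distance, "-")
                   for o in occ_r if o.distance == stratum])
        return occs, stratum
    occ_f = approximate_match(fwd, k, index, schemes, **options)
    occ_r = approximate_match(rev, k, index, schemes, **options)
    occs = occ_f + [Occurrence(o.start, o.end, o.distance, "-") for o in occ_r]
    return occs, (min(o.distance for o in occs) if occs else None)


def _to_hit(occ: Occurrence, read_seq: str, index: FmIndex) -> _Hit | None:
    rec = index.resolve_interval(occ.start, occ.end)
    if rec is None:
        return None
    oriented = read_seq if occ.strand == "+" else reverse_complement(read_seq)
    cost, cigar = align_global(encode(oriented),
                               index.codes[occ.start: occ.end])
    return _Hit(occ, rec.name, occ.start - rec.start, cigar)


def _order_hits(hits: list[_Hit]) -> list[_Hit]:
    return sorted(hits, key=lambda h: (h.occ.distance, h.occ.start,
                                       h.occ.strand == "-"))


def _base_record(read: ReadRecord, hit: _Hit, secondary: bool, mapq: int
                 ) -> SamRecord:
    flag = 0
    if hit.occ.strand == "-":
        flag |= FLAG_REVERSE
        seq = reverse_complement(read.sequence)
        qual = read.qualities[::-1] if read.qualities else "*"
    else:
        seq = read.sequence
        qual = read.qualities or "*"
    if secondary:
        flag |= FLAG_SECONDARY
        seq, qual = "*", "*"
    return SamRecord(
        qname=read.name, flag=flag, rname=hit.rname, pos=hit.local_start + 1,
        mapq=mapq, cigar=hit.cigar, seq=seq, qual=qual,
        tags={"NM": hit.occ.distance, "AS": -hit.occ.distance},
    )


def _unmapped_record(read: ReadRecord) -> SamRecord:
    return SamRecord(qname=read.name, flag=FLAG_UNMAPPED,
                     seq=read.sequence, qual=read.qualities or "*")


def map_single(read: ReadRecord, k_or_rate, mode: str, index: FmIndex,
               schemes=None, **options) -> list[SamRecord]:
    """Map one read on both strands; first record is primary."""
    k = resolve_error_budget(k_or_rate, len(read.sequence))
    occs, _ = _collect_hits(read.sequence, k, mode, index, schemes, **options)
    hits = [h for o in occs if (h := _to_hit(o, read.sequence, index))]
    if not hits:
        return [_unmapped_record(read)]
    hits = _order_hits(hits)
    best_d = hits[0].occ.distance
    n_best = sum(1 for h in hits if h.occ.distance == best_d)
    mapq = _mapq(n_best)
    return [_base_record(read, h, secondary=(i > 0), mapq=mapq if i == 0 else 0)
            for i, h in enumerate(hits)]


def infer_fragment_model(pairs: Iterable[tuple[ReadRecord, ReadRecord]],
                         index: FmIndex, k_or_rate=0.02, *, schemes=None,
                         max_pairs: int = 1000, min_observations: int = 50,
                         defaults: tuple[float, float] = DEFAULT_FRAGMENT_MODEL,
                         ) -> FragmentModel:
    """Estimate the fragment-size distribution from the first pairs.

    Uses up to ``max_pairs`` pairs in which both mates have a unique best
    alignment in convergent orientation on the same reference record; the
    outer distance (leftmost start to rightmost end) is the fragment length.
    Falls back to the documented defaults when fewer than
    ``min_observations`` pairs qualify.
    """
    lengths: list[int] = []
    for n, (r1, r2) in enumerate(pairs):
        if n >= max_pairs:
            break
        frag = _unique_convergent_fragment(r1, r2, index, k_or_rate, schemes)
        if frag is not None:
            lengths.append(frag)
    if len(lengths) < min_observations:
        return FragmentModel(defaults[0], defaults[1],
                             n_observations=len(lengths), fallback=True)
    arr = np.asarray(lengths, dtype=float)
    return FragmentModel(float(arr.mean()), float(arr.std(ddof=1)),
                         n_observations=len(arr))


def _unique_convergent_fragment(r1, r2, index, k_or_rate, schemes
                                ) -> int | None:
    out = []
    for read in (r1, r2):
        k = resolve_error_budget(k_or_rate, len(read.sequence))
        occs, _ = _collect_hits(read.sequence, k, "all-best", index, schemes)
        if len(occs) != 1:
            return None
        out.append(occs[0])
    o1, o2 = out
    left, right = (o1, o2) if o1.start <= o2.start else (o2, o1)
    if left.strand != "+" or right.strand != "-":
        return None
    if index.resolve_interval(left.start, right.end) is None:
        return None
    return right.end - left.start


def map_pair(read1: ReadRecord, read2: ReadRecord, k_or_rate, mode: str,
             fragment_model: FragmentModel, index: FmIndex, schemes=None,
             **options) -> list[SamRecord]:
    """Map a mate pair, reporting all optimal proper pairs.

    A proper pair is convergently oriented (leftmost mate forward) with an
    outer fragment length within the model window; optimality is the
    smallest d1 + d2.  Without any proper pair the mates are mapped
    independently (pair flags kept, proper-pair bit unset).
    """
    k1 = resolve_error_budget(k_or_rate, len(read1.sequence))
    k2 = resolve_error_budget(k_or_rate, len(read2.sequence))
    occ1, _ = _collect_hits(read1.sequence, k1, "all", index, schemes, **options)
    occ2, _ = _collect_hits(read2.sequence, k2, "all", index, schemes, **options)

    candidates: list[tuple[int, Occurrence, Occurrence, int]] = []
    for o1 in occ1:
        for o2 in occ2:
            left, right = (o1, o2) if o1.start <= o2.start else (o2, o1)
            if left.strand != "+" or right.strand != "-":
                continue
            if index.resolve_interval(left.start, right.end) is None:
                continue
            frag = right.end - left.start
            if not fragment_model.accepts(frag):
                continue
            candidates.append((o1.distance + o2.distance, o1, o2, frag))
    if not candidates:
        out = []
        for read, flag_mate in ((read1, FLAG_FIRST), (read2, FLAG_SECOND)):
            for rec in map_single(read, k_or_rate, mode, index, schemes,
                                  **options):
                rec.flag |= FLAG_PAIRED | flag_mate
                out.append(rec)
        return out

    best = min(c[0] for c in candidates)
    chosen = sorted((c for c in candidates if c[0] == best),
                    key=lambda c: (c[1].start, c[2].start))
    out: list[SamRecord] = []
    mapq = _mapq(len(chosen))
    for rank, (_, o1, o2, frag) in enumerate(chosen):
        secondary = rank > 0
        recs = []
        for read, own, other, flag_mate in ((read1, o1, o2, FLAG_FIRST),
                                            (read2, o2, o1, FLAG_SECOND)):
            hit = _to_hit(own, read.sequence, index)
            rec = _base_record(read, hit, secondary,
                               mapq if not secondary else 0)
            rec.flag |= FLAG_PAIRED | FLAG_PROPER | flag_mate
            if other.strand == "-":
                rec.flag |= FLAG_MATE_REVERSE
            other_rec = index.resolve_interval(other.start, other.end)
            rec.rnext = "=" if other_rec.name == hit.rname else other_rec.name
            rec.pnext = other.start - other_rec.start + 1
            # leftmost mate carries +fragment, rightmost -fragment
            if own.start != other.start:
                rec.tlen = frag if own.start < other.start else -frag
            else:
                rec.tlen = frag if flag_mate == FLAG_FIRST else -frag
            recs.append(rec)
        out.extend(recs)
    return out
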