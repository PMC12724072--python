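"""Search-scheme execution over the bidirectional index.

A search processes the pattern's parts in its pi order.  The first part fixes
an *anchor*: everything from the anchor rightwards forms the right wing,
everything before it (reversed) the left wing.  Each wing keeps one
bit-parallel banded edit-distance column (:class:`~lossmap.bitparallel.BitRow`)
between its full pattern block and the text characters spelled so far in that
direction.  Any alignment of the pattern against a candidate text window
splits at the anchor into independent left and right alignments, so the total
distance of a partial match is the sum of the two wings' cells and the two
column minima give a sound lower bound for pruning against the search's
cumulative upper bounds.

Once a state's bidirectional range holds fewer than ``in_text_threshold``
candidates (4 by default) the matcher locates them and finishes both wings
directly against the text slice instead of extending through the index;
the output is provably identical either way, only the code path differs.

States whose final distance falls below the search's last lower bound are
discarded at reporting time; the scheme's coverage guarantees another search
reports them.  Exact duplicates are removed and overlapping redundant
variants (a leading/trailing gap traded for a substitution shifts the window
by one) are collapsed to representatives by :func:`cluster_occurrences`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .alphabet import EXTENDABLE, encode
from .bitparallel import BitRow, band_row_update  # noqa: F401 (re-export)
from .index import BidirectionalRange, FmIndex
from .schemes import (MAX_K, Partition, Search, SearchScheme,
                      dynamic_partition, pigeonhole_scheme, select_scheme,
                      uniform_partition)

DEFAULT_IN_TEXT_THRESHOLD = 4


@dataclass(frozen=True, order=True)
class Occurrence:
    """A located alignment: half-open reference interval, distance, strand."""

    start: int
    end: int
    distance: int
    strand: str = "+"


class _SearchRun:
    """Executes one search of a scheme for one pattern; collects raw
    (start, end, distance) triples in concatenated-text coordinates."""

    def __init__(self, search: Search, partition: Partition,
                 pattern_codes: np.ndarray, index: FmIndex, k: int,
                 in_text_threshold: int) -> None:
        cuts = partition.cuts
        order = search.pi
        self.index = index
        self.k = k
        self.threshold = in_text_threshold
        self.anchor_cut = cuts[order[0]]
        a = self.anchor_cut
        self.right_pat = pattern_codes[a:]
        self.left_pat = pattern_codes[:a][::-1]
        self.m_r = len(self.right_pat)
        self.m_l = len(self.left_pat)
        self.dirs = ["R" if q >= order[0] else "L" for q in order]
        self.targets = [cuts[q + 1] - a if q >= order[0] else a - cuts[q]
                        for q in order]
        self.last_step = {
            w: max((t for t, d in enumerate(self.dirs) if d == w), default=None)
            for w in "RL"
        }
        self.p = len(order)
        self.U = [min(u, k) for u in search.U]
        self.L_final = search.L[-1]
        self.cap = self.U[-1]
        self.out: list[tuple[int, int, int]] = []

    # -- helpers -----------------------------------------------------------

    def _extend_rng(self, rng: BidirectionalRange, c: int, wing: str
                    ) -> BidirectionalRange:
        if wing == "R":
            return self.index.extend_right(rng, c)
        return self.index.extend_left(rng, c)

    def run(self) -> list[tuple[int, int, int]]:
        rng = self.index.full_range()
        # exact prefix: while the cumulative upper bound is 0 every processed
        # character must match, so no DP state is needed yet
        jl = jr = 0
        t = 0
        while t < self.p and self.U[t] == 0:
            wing = self.dirs[t]
            target = self.targets[t]
            j = jr if wing == "R" else jl
            while j < target:
                if rng.width < self.threshold:
                    self._in_text(self._make_state(t, rng, jl, jr))
                    return self.out
                c = int(self.right_pat[j] if wing == "R"
                        else self.left_pat[j])
                if not 1 <= c <= 4:
                    return self.out  # ambiguous base can never match exactly
                rng = self._extend_rng(rng, c, wing)
                if rng.empty:
                    return self.out
                j += 1
            if wing == "R":
                jr = j
            else:
                jl = j
            t += 1
        if t == self.p:
            # fully exact search (k bound 0 throughout)
            if self.L_final <= 0 and not rng.empty:
                self._report(rng, jl, jr, 0)
            return self.out
        self._process(self._make_state(t, rng, jl, jr))
        return self.out

    def _make_state(self, t, rng, jl, jr):
        row_r = BitRow.after_exact(self.right_pat, jr)
        row_l = BitRow.after_exact(self.left_pat, jl) if self.m_l else None
        return (t, rng, row_l, row_r)

    def _other_contrib(self, t: int, wing: str, row_l, row_r) -> int:
        """Contribution of the inactive wing: exact once all of its parts are
        processed (its final cell), otherwise a lower bound (its column
        minimum)."""
        other = "L" if wing == "R" else "R"
        row = row_l if other == "L" else row_r
        if row is None:
            return 0
        last_step = self.last_step[other]
        if last_step is None or t > last_step:
            return row.last
        return row.minimum()

    def _report(self, rng: BidirectionalRange, jl: int, jr: int, d: int
                ) -> None:
        for s0 in self.index.locate(rng):
            self.out.append((s0, s0 + jl + jr, d))

    # -- index-space exploration -------------------------------------------

    def _process(self, state) -> None:
        # Part completions are *windows*, not single text lengths: an
        # alignment with e errors so far may cross a part's pattern boundary
        # with up to e net inserted or deleted characters, so a step
        # transition is spawned at every spelled length within U[t] of the
        # boundary (while the same state also keeps extending).  The spawned
        # branch and the extending branch share the wing's full-block row, so
        # no cell information is lost at direction switches.
        stack = [state]
        while stack:
            t, rng, row_l, row_r = stack.pop()
            if rng.empty:
                continue
            if rng.width < self.threshold:
                self._in_text((t, rng, row_l, row_r))
                continue
            wing = self.dirs[t]
            row = row_r if wing == "R" else row_l
            other = self._other_contrib(t, wing, row_l, row_r)
            target = self.targets[t]
            ub = self.U[t]
            final = t == self.p - 1

            if target - ub <= row.j <= target + ub:
                if final:
                    d = row.last + other
                    if self.L_final <= d <= self.cap:
                        jl = row_l.j if row_l is not None else 0
                        self._report(rng, jl, row_r.j, d)
                else:
                    boundary = int(row.values()[target])
                    if boundary + other <= ub:
                        stack.append((t + 1, rng, row_l, row_r))
            if row.j >= target + ub:
                continue  # beyond the boundary's error window

            for c in EXTENDABLE:
                nrng = self._extend_rng(rng, c, wing)
                if nrng.empty:
                    continue
                nrow = row.advance(c)
                if nrow.minimum() + other > ub:
                    continue
                if wing == "R":
                    stack.append((t, nrng, row_l, nrow))
                else:
                    stack.append((t, nrng, nrow, row_r))

    # -- in-text verification ----------------------------------------------

    def _wing_completions(self, row: BitRow, m: int, chars: Iterable[int]
                          ) -> list[tuple[int, int]]:
        """All (text_length, final_cell) completions of a wing against the
        actual text characters, within the distance budget."""
        budget = self.cap
        res: list[tuple[int, int]] = []
        chars = iter(chars)
        while True:
            if row.last <= budget:
                res.append((row.j, row.last))
            if row.j >= m + budget:
                break
            c = next(chars, None)
            if c is None:
                break
            row = row.advance(int(c))
            if row.minimum() > budget:
                break
        return res

    def _in_text(self, state) -> None:
        t, rng, row_l, row_r = state
        if rng.empty:
            return
        codes = self.index.codes
        n = self.index.n
        jl = row_l.j if row_l is not None else 0
        jr = row_r.j
        r_done = self.last_step["R"] is not None and t > self.last_step["R"]
        l_done = self.last_step["L"] is None or t > self.last_step["L"]
        for s0 in self.index.locate(rng):
            anchor = s0 + jl
            if r_done:
                rights = [(jr, row_r.last)]
            else:
                rights = self._wing_completions(
                    row_r, self.m_r, codes[anchor + jr: n - 1])
            if not rights:
                continue
            if row_l is None:
                lefts = [(0, 0)]
            elif l_done:
                lefts = [(jl, row_l.last)]
            else:
                lefts = self._wing_completions(
                    row_l, self.m_l, codes[s0 - 1::-1] if s0 > 0 else ())
            for ll, vl in lefts:
                for rr, vr in rights:
                    d = vl + vr
                    if self.L_final <= d <= self.cap:
                        self.out.append((anchor - ll, anchor + rr, d))


def execute_search(search: Search, partition: Partition, pattern: str,
                   index: FmIndex, k: int, *,
                   in_text_threshold: int = DEFAULT_IN_TEXT_THRESHOLD
                   ) -> list[tuple[int, int, int]]:
    """Run one search; returns raw (start, end, distance) candidate triples."""
    codes = pattern if isinstance(pattern, np.ndarray) else encode(pattern)
    run = _SearchRun(search, partition, codes, index, k, in_text_threshold)
    return run.run()


def switch_to_in_text(rng: BidirectionalRange,
                      threshold: int = DEFAULT_IN_TEXT_THRESHOLD) -> bool:
    """Should index-space extension hand over to in-text verification?"""
    return rng.width < threshold


def dedupe(occurrences: Iterable[Occurrence]) -> list[Occurrence]:
    """Collapse exact duplicates (same start, end, distance, strand)."""
    return sorted(set(occurrences))


def cluster_occurrences(occurrences: Sequence[Occurrence],
                        read_length: int | None = None) -> list[Occurrence]:
    """Group overlapping occurrences and keep representatives.

    Within each chain of mutually overlapping intervals only the occurrences
    at the chain-minimal distance survive; among surviving equal-distance
    variants that still overlap each other, the leftmost-starting (then
    longest) one represents the group.  Non-overlapping occurrences are never
    merged.  Every suppressed occurrence overlaps a reported representative
    of no larger distance, which is the covering sense in which clustering
    preserves losslessness.
    """
    by_strand: dict[str, list[Occurrence]] = {}
    for occ in occurrences:
        by_strand.setdefault(occ.strand, []).append(occ)
    reps: list[Occurrence] = []
    for occs in by_strand.values():
        occs.sort(key=lambda o: (o.start, o.end))
        chain: list[Occurrence] = []
        chain_end = -1
        for occ in occs + [None]:
            if occ is not None and (not chain or occ.start < chain_end):
                chain.append(occ)
                chain_end = max(chain_end, occ.end)
                continue
            if chain:
                dmin = min(o.distance for o in chain)
                best = [o for o in chain if o.distance == dmin]
                sub_end = -1
                for o in best:  # already (start, end)-sorted
                    if o.start >= sub_end:
                        reps.append(o)
                    sub_end = max(sub_end, o.end)
            if occ is not None:
                chain = [occ]
                chain_end = occ.end
    return sorted(reps)


def _resolve_schemes(schemes, k: int) -> list[SearchScheme]:
    if schemes is None:
        return [pigeonhole_scheme(k)]
    if isinstance(schemes, SearchScheme):
        candidates = [schemes]
    elif isinstance(schemes, dict):
        candidates = list(schemes.get(k) or [pigeonhole_scheme(k)])
    else:
        candidates = list(schemes)
    for s in candidates:
        if s.k != k:
            raise ValueError(f"scheme {s.name or s} is for k={s.k}, not {k}")
    return candidates


def approximate_match(pattern: str, k: int, index: FmIndex, schemes=None, *,
                      partition="dynamic", dynamic_selection: bool = True,
                      in_text_threshold: int = DEFAULT_IN_TEXT_THRESHOLD,
                      cluster: bool = True) -> list[Occurrence]:
    """All mode: every occurrence of the pattern within edit distance k.

    Pipeline: partition (dynamic workload balancing by default) -> scheme
    selection -> all searches -> boundary filtering -> dedupe -> clustering.
    With ``cluster=False`` the full deduplicated occurrence list is returned;
    its end-position set is exactly the set of text positions where some
    window aligns within distance k.
    """
    if not 0 <= k <= MAX_K:
        raise ValueError(f"k must be in 0..{MAX_K}, got {k}")
    if len(pattern) <= k:
        raise ValueError("pattern must be longer than the error budget")
    candidates = _resolve_schemes(schemes, k)
    p = candidates[0].p
    if any(s.p != p for s in candidates):
        raise ValueError("candidate schemes must agree on the part count")
    if len(pattern) < p:
        raise ValueError(f"pattern of length {len(pattern)} cannot be split "
                         f"into {p} parts")
    if isinstance(partition, Partition):
        part = partition
    elif partition == "dynamic":
        part = dynamic_partition(pattern, p, index)
    else:
        part = uniform_partition(len(pattern), p)
    if len(candidates) > 1 and dynamic_selection:
        scheme = select_scheme(candidates, pattern, part, index)
    else:
        scheme = candidates[0]
    codes = encode(pattern)
    raw: list[tuple[int, int, int]] = []
    for search in scheme.searches:
        raw.extend(execute_search(search, part, codes, index, k,
                                  in_text_threshold=in_text_threshold))
    occs = [Occurrence(s, e, d) for s, e, d in raw
            if index.resolve_interval(s, e) is not None]
    occs = dedupe(occs)
    if cluster:
        occs = cluster_occurrences(occs, len(pattern))
    return occs


def align_global(pattern_codes: np.ndarray, text_codes: np.ndarray
                 ) -> tuple[int, str]:
    """Global alignment of a read against its located reference window.

    Returns ``(cost, cigar)`` under unit edit costs.  Traceback prefers
    match > substitution > deletion (reference consumed) > insertion, and
    'M' covers both match and mismatch (the NM tag carries the distance).
    """
    pat = np.asarray(pattern_codes, dtype=np.int16)
    txt = np.asarray(text_codes, dtype=np.int16)
    m, n = len(pat), len(txt)
    D = np.empty((m + 1, n + 1), dtype=np.int32)
    D[0] = np.arange(n + 1)
    cols = np.arange(n + 1)
    for i in range(1, m + 1):
        # A/C/G/T match only themselves; X/N match nothing, not even X
        match = (txt == pat[i - 1]) & (pat[i - 1] >= 1) & (pat[i - 1] <= 4)
        diag = D[i - 1, :-1] + (~match)
        up = D[i - 1, 1:] + 1
        t = np.minimum(diag, up)
        # horizontal dependency resolved by a running-minimum scan
        w = np.minimum.accumulate(np.concatenate(([i], t - cols[1:])))
        D[i] = w + cols
    i, j = m, n
    ops: list[str] = []
    while i > 0 or j > 0:
        here = D[i, j]
        if i > 0 and j > 0:
            is_match = bool(pat[i - 1] == txt[j - 1]) and 1 <= pat[i - 1] <= 4
            if here == D[i - 1, j - 1] + (0 if is_match else 1):
                ops.append("M")
                i -= 1
                j -= 1
                continue
        if j > 0 and here == D[i, j - 1] + 1:
            ops.append("D")
            j -= 1
            continue
        ops.append("I")
        i -= 1
    ops.reverse()
    cigar = []
    for op in ops:
        if cigar and cigar[-1][1] == op:
            cigar[-1][0] += 1
        else:
            cigar.append([1, op])
    return int(D[m, n]), "".join(f"{c}{o}" for c, o in cigar)


def all_best_match(pattern: str, k_max: int, index: FmIndex, schemes=None,
                   **options) -> tuple[list[Occurrence], int | None]:
    """All-best mode: strata-based search for the minimal-distance hits.

    Runs the all-mode matcher at k = 0, 1, ... until the first non-empty
    stratum and returns only the occurrences at that distance, together with
    the stratum value (None if nothing aligns within k_max).
    """
    for k in range(0, k_max + 1):
        occs = approximate_match(pattern, k, index, schemes, **options)
        if occs:
            stratum = min(o.distance for o in occs)
            return [o for o in occs if o.distance == stratum], stratum
    return [], None
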