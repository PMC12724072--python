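"""Search schemes: representation, validation, coverage, generation, files.

A *search* is a triple (pi, L, U): a part-processing order plus cumulative
lower/upper error bounds after each processed part.  A *search scheme* for k
errors is a set of searches that jointly admit every distribution of <= k
errors over the p pattern parts, which is what makes the matcher lossless.

Scheme file dialect (the original publications do not fix one): one search
per line as three brace-delimited comma-separated integer lists --

    {1,2,3} {0,0,0} {0,1,2}

with 1-based part numbers in pi, '#' comments, one scheme per file, and the
file stem carrying k (``3.txt``, ``k3.txt`` or ``k3_variant.txt``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

MAX_K = 13  # hard ceiling of the supported error budget


class SchemeError(ValueError):
    pass


@dataclass(frozen=True)
class Search:
    """One search: processing order pi (0-based internally) and bounds."""

    pi: tuple[int, ...]
    L: tuple[int, ...]
    U: tuple[int, ...]

    @property
    def p(self) -> int:
        return len(self.pi)

    def admits(self, errors_per_part) -> bool:
        """Does this search admit the given per-part error vector?"""
        cum = 0
        for i, part in enumerate(self.pi):
            cum += errors_per_part[part]
            if not self.L[i] <= cum <= self.U[i]:
                return False
        return True

    def __str__(self) -> str:
        fmt = lambda xs: "{" + ",".join(str(x) for x in xs) + "}"
        return f"{fmt(tuple(q + 1 for q in self.pi))} {fmt(self.L)} {fmt(self.U)}"


def validate_search(search: Search, p: int) -> str | None:
    """Return None if valid, else a description of the first violated rule."""
    if len(search.pi) != p or len(search.L) != p or len(search.U) != p:
        return f"pi/L/U must all have length p={p}"
    if sorted(search.pi) != list(range(p)):
        return f"pi={search.pi} is not a permutation of 0..{p - 1}"
    lo = hi = search.pi[0]
    for q in search.pi[1:]:
        if q == lo - 1:
            lo = q
        elif q == hi + 1:
            hi = q
        else:
            return (f"connectivity violation: part {q + 1} is not adjacent to "
                    f"the processed interval {lo + 1}..{hi + 1}")
    for name, arr in (("L", search.L), ("U", search.U)):
        if any(b < a for a, b in zip(arr, arr[1:])):
            return f"{name}={arr} must be non-decreasing"
    if any(l > u for l, u in zip(search.L, search.U)):
        return f"L must not exceed U ({search.L} vs {search.U})"
    if search.L[0] < 0:
        return "bounds must be non-negative"
    return None


@dataclass(frozen=True)
class SearchScheme:
    """A validated collection of searches for a fixed error budget k."""

    k: int
    searches: tuple[Search, ...]
    name: str = ""

    @property
    def p(self) -> int:
        return self.searches[0].p

    def validate(self) -> None:
        if not self.searches:
            raise SchemeError("scheme has no searches")
        p = self.searches[0].p
        for i, s in enumerate(self.searches):
            if s.p != p:
                raise SchemeError(f"search {i} has {s.p} parts, expected {p}")
            msg = validate_search(s, p)
            if msg is not None:
                raise SchemeError(f"search {i} ({s}): {msg}")


def _vector_chunks(p: int, k: int, max_chunk: int = 1_000_000,
                   _prefix: tuple[int, ...] = ()) -> Iterator[np.ndarray]:
    """All non-negative integer vectors of length p with sum <= k, yielded as
    (N, p) arrays of bounded size via recursive splitting on the first part."""
    from math import comb

    total = comb(k + p, p)
    if total <= max_chunk:
        rows = np.zeros((1, 0), dtype=np.int16)
        rem = np.array([k], dtype=np.int16)
        for _ in range(p):
            reps = rem + 1
            starts = np.repeat(np.cumsum(reps) - reps, reps)
            vals = (np.arange(reps.sum()) - starts).astype(np.int16)
            rows = np.repeat(rows, reps, axis=0)
            rows = np.hstack([rows, vals[:, None]])
            rem = np.repeat(rem, reps) - vals
        if _prefix:
            pref = np.tile(np.array(_prefix, dtype=np.int16), (len(rows), 1))
            rows = np.hstack([pref, rows])
        yield rows
        return
    for a in range(k + 1):
        yield from _vector_chunks(p - 1, k - a, max_chunk, _prefix + (a,))


def covers(scheme: SearchScheme, k: int | None = None
           ) -> tuple[bool, tuple[int, ...] | None]:
    """Exhaustively test whether the scheme admits every error distribution.

    Enumerates all vectors (a_1..a_p) with sum <= k and checks each against
    every search; returns ``(True, None)`` or ``(False, witness_vector)``.
    The enumeration is chunked and numpy-vectorized so the full check stays
    exact up to k = 13 (about 20 million vectors at p = 14).
    """
    scheme.validate()
    if k is None:
        k = scheme.k
    p = scheme.p
    for chunk in _vector_chunks(p, k):
        cum_ok = np.zeros(len(chunk), dtype=bool)
        for s in scheme.searches:
            order = np.array(s.pi)
            cum = np.cumsum(chunk[:, order], axis=1)
            lo = np.array(s.L, dtype=np.int16)
            hi = np.array(s.U, dtype=np.int16)
            cum_ok |= ((cum >= lo) & (cum <= hi)).all(axis=1)
            if cum_ok.all():
                break
        if not cum_ok.all():
            witness = tuple(int(x) for x in chunk[np.flatnonzero(~cum_ok)[0]])
            return False, witness
    return True, None


def pigeonhole_scheme(k: int, p: int | None = None) -> SearchScheme:
    """The pigeonhole scheme: p = k+1 parts (by default), one search per
    part; search j matches part j first exactly (U starts at 0), then sweeps
    right to the last part and finally left, with up to k cumulative errors.

    Any p > k works too (some part must then still be error-free), which
    provides structurally different covering schemes for the same k.
    """
    if not 0 <= k <= MAX_K:
        raise SchemeError(f"k must be in 0..{MAX_K}, got {k}")
    if p is None:
        p = k + 1
    if p <= k:
        raise SchemeError(f"pigeonhole construction needs p > k (p={p}, k={k})")
    searches = []
    for j in range(p):
        pi = tuple(range(j, p)) + tuple(range(j - 1, -1, -1))
        L = (0,) * p
        U = (0,) + (k,) * (p - 1)
        searches.append(Search(pi, L, U))
    scheme = SearchScheme(k, tuple(searches), name=f"pigeonhole-k{k}-p{p}")
    scheme.validate()
    return scheme


# -- scheme files ----------------------------------------------------------

_LINE_RE = re.compile(r"^\s*\{([\d,\s]*)\}\s*\{([\d,\s]*)\}\s*\{([\d,\s]*)\}\s*$")
_STEM_RE = re.compile(r"^k?(\d+)")


def parse_scheme_file(path: str | Path, k: int | None = None,
                      check_coverage: bool = True) -> SearchScheme:
    """Parse one scheme file; see the module docstring for the dialect."""
    path = Path(path)
    if k is None:
        m = _STEM_RE.match(path.stem)
        if not m:
            raise SchemeError(f"{path}: cannot infer k from file name")
        k = int(m.group(1))
    searches = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        m = _LINE_RE.match(stripped)
        if not m:
            raise SchemeError(f"{path}:{lineno}: expected three brace lists, "
                              f"got {line!r}")
        pi, L, U = (tuple(int(x) for x in g.replace(" ", "").split(",") if x)
                    for g in m.groups())
        searches.append(Search(tuple(q - 1 for q in pi), L, U))
    scheme = SearchScheme(k, tuple(searches), name=path.stem)
    try:
        scheme.validate()
    except SchemeError as exc:
        raise SchemeError(f"{path}: {exc}") from None
    if check_coverage:
        ok, witness = covers(scheme, k)
        if not ok:
            raise SchemeError(
                f"{path}: scheme does not cover k={k}; uncovered error "
                f"distribution {witness}")
    return scheme


def parse_scheme_collection(path: str | Path, check_coverage: bool = True
                            ) -> dict[int, list[SearchScheme]]:
    """Load every ``*.txt`` scheme file under a directory, keyed by k."""
    path = Path(path)
    files = sorted(path.glob("*.txt")) if path.is_dir() else [path]
    if not files:
        raise SchemeError(f"{path}: no scheme files found")
    out: dict[int, list[SearchScheme]] = {}
    for f in files:
        scheme = parse_scheme_file(f, check_coverage=check_coverage)
        out.setdefault(scheme.k, []).append(scheme)
    return out


def write_scheme(scheme: SearchScheme, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{s}\n" for s in scheme.searches))


# -- partitioning ----------------------------------------------------------

@dataclass(frozen=True)
class Partition:
    """p+1 cut positions over a pattern, defining parts left to right."""

    cuts: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.cuts, self.cuts[1:])):
            raise ValueError(f"parts must be non-empty: cuts={self.cuts}")

    @property
    def p(self) -> int:
        return len(self.cuts) - 1

    def parts(self, pattern: str) -> list[str]:
        return [pattern[a:b] for a, b in zip(self.cuts, self.cuts[1:])]


def uniform_partition(pattern_length: int, p: int) -> Partition:
    """Equal-sized parts, any remainder distributed left to right."""
    if not 1 <= p <= pattern_length:
        raise ValueError(f"need 1 <= p <= pattern length "
                         f"({p} parts for length {pattern_length})")
    base, extra = divmod(pattern_length, p)
    cuts = [0]
    for i in range(p):
        cuts.append(cuts[-1] + base + (1 if i < extra else 0))
    return Partition(tuple(cuts))


def dynamic_partition(pattern: str, p: int, index, *,
                      tolerance: int = 4, budget: int | None = None) -> Partition:
    """Workload-balancing partition: starting from uniform cuts, greedily
    widen the part with the most exact matches in the text at the expense of
    its smaller neighbour, one column at a time, until the counts are within
    a factor ``tolerance`` of each other or the move budget (2p) is spent.

    The partition only affects runtime, never the reported occurrences.
    """
    part = uniform_partition(len(pattern), p)
    if p == 1:
        return part
    if budget is None:
        budget = 2 * p
    cuts = list(part.cuts)
    counts = [index.count_exact(pattern[a:b])
              for a, b in zip(cuts, cuts[1:])]
    if sum(counts) == 0:
        return part
    for _ in range(budget):
        mx = max(counts)
        mn = min(counts)
        if mn > 0 and mx <= tolerance * mn:
            break
        i = counts.index(mx)
        # candidate neighbours that can cede a column
        moves = []
        if i > 0 and cuts[i] - cuts[i - 1] > 1:
            moves.append((counts[i - 1], i - 1))
        if i < p - 1 and cuts[i + 2] - cuts[i + 1] > 1:
            moves.append((counts[i + 1], i + 1))
        if not moves:
            break
        _, j = min(moves)
        trial = list(cuts)
        if j == i - 1:
            trial[i] -= 1
        else:
            trial[i + 1] += 1
        new_i = index.count_exact(pattern[trial[i]:trial[i + 1]])
        new_j = index.count_exact(pattern[trial[j]:trial[j + 1]])
        new_counts = list(counts)
        new_counts[i], new_counts[j] = new_i, new_j
        if max(new_counts) >= mx:
            break  # no move improves balance; keep current cuts
        cuts, counts = trial, new_counts
    return Partition(tuple(cuts))


def select_scheme(candidates, pattern: str, partition: Partition, index
                  ) -> SearchScheme:
    """Pick the candidate scheme with the lowest estimated workload: the sum
    over its searches of the exact-match count of each search's first part.
    Ties break deterministically by candidate order."""
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate schemes")
    ps = {s.p for s in candidates}
    if len(ps) != 1 or ps != {partition.p}:
        raise ValueError("candidate schemes must share the partition's p")
    parts = partition.parts(pattern)
    best = None
    for rank, scheme in enumerate(candidates):
        est = sum(index.count_exact(parts[s.pi[0]]) for s in scheme.searches)
        if best is None or est < best[0]:
            best = (est, rank, scheme)
    return best[2]
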