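"""Independent brute-force oracles used to check the aligner.

Everything here deliberately avoids the package's own code paths: plain
rotation sorts, sliding-window scans and quadratic DP, vectorized with numpy
only where the acceptance workload needs it.
"""

from __future__ import annotations

import itertools

import numpy as np


def naive_suffix_array(text: str) -> list[int]:
    return sorted(range(len(text)), key=lambda i: text[i:])


def naive_bwt(text: str) -> str:
    """Last column of the lexicographically sorted rotations."""
    rotations = sorted(text[i:] + text[:i] for i in range(len(text)))
    return "".join(r[-1] for r in rotations)


def sliding_count(text: str, pattern: str) -> int:
    if not pattern:
        return len(text) + 1
    return sum(1 for i in range(len(text) - len(pattern) + 1)
               if text[i:i + len(pattern)] == pattern)


def sliding_positions(text: str, pattern: str) -> set[int]:
    return {i for i in range(len(text) - len(pattern) + 1)
            if text[i:i + len(pattern)] == pattern}


def edit_distance(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j - 1] + (ca != cb), prev[j] + 1,
                           cur[-1] + 1))
        prev = cur
    return prev[-1]


def scalar_dp_columns(pattern: str, text: str) -> list[list[int]]:
    """All columns D[0..m][j] of the global DP matrix, one per text prefix.

    Column j holds the distances between every pattern prefix and text[:j];
    this is the scalar reference for the bit-parallel row update.
    """
    m = len(pattern)
    col = list(range(m + 1))
    out = [col[:]]
    for j, ct in enumerate(text, 1):
        new = [j]
        for i in range(1, m + 1):
            sub = 0 if pattern[i - 1] == ct else 1
            new.append(min(col[i - 1] + sub, col[i] + 1, new[-1] + 1))
        col = new
        out.append(col[:])
    return out


def sellers_end_positions(text: str, pattern: str, k: int) -> set[int]:
    """Free-start semi-global DP scan: all end positions e such that some
    window of the text ending at e is within distance k of the pattern."""
    m, n = len(pattern), len(text)
    t = np.frombuffer(text.encode(), dtype=np.uint8)
    p = np.frombuffer(pattern.encode(), dtype=np.uint8)
    row = np.zeros(n + 1, dtype=np.int32)  # D[0][j] = 0: free start
    cols = np.arange(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        diag = row[:-1] + (t != p[i - 1])
        up = row[1:] + 1
        best = np.minimum(diag, up)
        shifted = np.concatenate(([np.int32(i)], best - cols[1:]))
        row = np.minimum.accumulate(shifted) + cols
    return {int(j) for j in np.flatnonzero(row <= k)}


def occurrence_map(text: str, pattern: str, k: int) -> dict[tuple[int, int], int]:
    """Minimal distance for every window (start, end) within distance k.

    Quadratic per end position; only for small instances.
    """
    out: dict[tuple[int, int], int] = {}
    m = len(pattern)
    for s in range(len(text) + 1):
        # one DP anchored at s with a free end
        suffix = text[s:]
        full = [[0] * (len(suffix) + 1) for _ in range(m + 1)]
        full[0] = list(range(len(suffix) + 1))
        for i in range(1, m + 1):
            full[i][0] = i
            for j in range(1, len(suffix) + 1):
                sub = 0 if pattern[i - 1] == suffix[j - 1] else 1
                full[i][j] = min(full[i - 1][j - 1] + sub,
                                 full[i - 1][j] + 1, full[i][j - 1] + 1)
        for j in range(len(suffix) + 1):
            if full[m][j] <= k:
                key = (s, s + j)
                out[key] = min(out.get(key, k + 1), full[m][j])
    return out


def brute_covers(searches, k: int) -> tuple[bool, tuple[int, ...] | None]:
    """Pure-python coverage check over all error vectors (cross-check).

    ``searches`` is a list of (pi, L, U) with 0-based pi.
    """
    p = len(searches[0][0])
    for vec in itertools.product(range(k + 1), repeat=p):
        if sum(vec) > k:
            continue
        hit = False
        for pi, L, U in searches:
            cum = 0
            ok = True
            for i, part in enumerate(pi):
                cum += vec[part]
                if not L[i] <= cum <= U[i]:
                    ok = False
                    break
            if ok:
                hit = True
                break
        if not hit:
            return False, vec
    return True, None


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def mutate(rng, seq: str, n_ops: int) -> str:
    out = list(seq)
    for _ in range(n_ops):
        op = rng.choice("sid")
        if not out:
            break
        pos = rng.randrange(len(out))
        if op == "s":
            out[pos] = rng.choice("ACGT")
        elif op == "i":
            out.insert(pos, rng.choice("ACGT"))
        elif len(out) > 2:
            del out[pos]
    return "".join(out)
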