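# Methods

This note documents the model behind `lossmap`, the numerical and design
choices that were genuinely open, and what the test suite does and does
not establish.

## Problem statement

Given a reference text `T` (one or more DNA records concatenated, total
length `n`) and a read `P`, *lossless approximate pattern matching*
reports every window `T[s:e)` whose unit-cost edit distance (Levenshtein:
substitutions, insertions, deletions) to `P` is at most a budget `k`.
*All-best* reporting returns only the windows at the minimal achievable
distance (the *stratum*). The budget is capped at `k = 13`, which at
Illumina read lengths corresponds to error rates up to roughly 8% and
keeps the banded machinery and the scheme library small; the cap also
means spliced alignment (arbitrarily long gaps) is out of scope.

## Search schemes

`P` is partitioned into `p` contiguous parts. A **search** is a triple
`(π, L, U)`: `π` orders the parts subject to *connectivity* (each next
part is adjacent to the interval of already-processed parts, so a
bidirectional index can always extend the partial match at one of its two
ends); `L` and `U` are non-decreasing cumulative lower/upper bounds on
the number of errors after each processed part, with `L[i] ≤ U[i]`. A
**scheme** covers budget `k` when, for every error vector
`(a1…ap)` with `Σ ai ≤ k`, some search admits it, i.e. all its cumulative
sums in `π`-order respect that search's bounds. Coverage implies every
qualifying window is found by at least one search — this is the
losslessness argument, and it is machine-checked: `covers()` enumerates
*all* error vectors (chunked, numpy-vectorized; ~20 M vectors at
`k = 13`) and returns a concrete uncovered witness on failure.

The bundled generator produces **pigeonhole schemes**: `p = k + 1` parts,
one search per part, each matching its part first exactly (`U` starts at
0) and then sweeping outward with up to `k` cumulative errors. Any
`p > k` also works and gives structurally different covering schemes,
which the invariance tests exploit. Externally designed (e.g.
ILP-optimized) schemes are *loaded*, not designed here: one search per
line as three brace-delimited lists (`{1,2,3} {0,0,0} {0,1,2}`, 1-based
`π`, `#` comments), one scheme per file, `k` in the file stem. Every
loaded scheme is validated and coverage-checked before use; a
non-covering file is rejected with the witness vector.

## Bidirectional index

The index stores the BWT of the sanitized text and of its reverse,
per-character prefix-count arrays (block size 1, O(1) rank — desk-scale
memory was deliberately traded for simplicity), cumulative character
counts, and a suffix array subsampled at factor 4 by default. Suffix
arrays are built by numpy prefix doubling; any correct sorter would do,
and tests cross-check against a naive rotation sort. A partial match is a
pair of synchronized half-open SA intervals (forward and reverse text) of
equal width; extending by one character on either side costs one rank
query per alphabet character. `locate` LF-walks each interval row to the
nearest sampled entry.

Sanitization: sequences are upper-cased; every non-ACGT character (N and
IUPAC codes) becomes a reserved fifth letter `X` that matches nothing,
*including another `X`*, so alignments across ambiguous bases always pay
an error — this keeps "all windows within distance k" well defined. Reads
are treated the same way. Multi-record references are concatenated with a
single terminal sentinel; instead of per-record separators, any located
occurrence whose interval crosses a record boundary is discarded.

## Matching

The first part processed by a search fixes an **anchor**. Everything from
the anchor rightward is the right wing, everything before it (reversed)
the left wing. Any alignment of `P` against a candidate window splits at
the anchor into two independent alignments, one per wing, so each wing
carries one bit-parallel edit-distance column (Myers delta vectors over a
Python integer, so any read length is one "word") between its *full*
pattern block and the text spelled so far in that direction. Because
every DP cell satisfies `D[i][j] ≥ |i − j|`, a full-width column is
exactly the banded computation with half-width `k`: no explicit band
bookkeeping, and the column minimum is a sound lower bound on any
completion.

Bound semantics during the walk:

- While the cumulative upper bound is still 0, characters are matched
  exactly through the index with no DP state (the pigeonhole fast path).
- A part completion is a *window*, not a single length: an alignment with
  `e` errors may cross a part's pattern boundary with up to `e` net
  indels, so the transition to the next search step is spawned at every
  spelled length within `U[t]` of the boundary, while the same state also
  keeps extending. The spawned and the extending branch share the wing's
  row, so direction switches lose no information.
- Pruning: a branch dies when the active column minimum plus the other
  wing's contribution (exact final cell if that wing is finished, else
  its column minimum) exceeds the current cumulative bound. This is
  deliberately *more permissive* than the bounds' strict reading — it can
  let a search report occurrences another search was "responsible" for —
  which affects only duplicate volume (removed by dedupe/clustering),
  never the final set.
- Lower bounds are enforced as the final reporting filter
  (`L[p] ≤ d ≤ U[p]`); coverage guarantees occurrences below a search's
  final lower bound are reported by another search.

When a state's range width drops below the **in-text threshold**
(default 4), each candidate is located and both wings are finished
directly against the text slice, enumerating all completion lengths
within budget. In-text verification applies only the total budget, not
the remaining per-part bounds — again harmless over-reporting. The
threshold changes the code path, never the output; the acceptance suite
checks thresholds 1 (never switch early), 4 and 64 for identical results.

Exact duplicates `(start, end, d, strand)` are removed. Overlapping
redundant variants (a leading/trailing gap exchanged for a substitution
shifts a window by one) are **clustered**: within each chain of mutually
overlapping intervals, only occurrences at the chain-minimal distance
survive, and among surviving equal-distance variants that still overlap,
the leftmost-starting (then longest) one represents the group. Every
suppressed occurrence overlaps a representative of no larger distance —
the covering sense in which clustering preserves losslessness. The
unclustered, deduplicated output (`cluster=False`) carries the exact
end-position set, which is what the oracle-equality tests compare.

All-best re-runs the matcher per stratum (`k = 0, 1, …` until non-empty);
whether work could be shared across strata is an open efficiency
question, answered here in favour of simplicity and correctness.

CIGAR strings come from a final full-DP traceback against the located
slice, with tie preference match > substitution > deletion > insertion;
`M` covers match and mismatch, and `NM` carries the distance.

## Read-level conventions

- Both strands are searched (the reverse complement is aligned as its own
  pattern); the primary record is the smallest distance, ties broken by
  leftmost reference position, then forward strand. How the original
  tools break such ties is not standardized; this rule is ours and
  documented, nothing more.
- MAPQ cannot be probabilistic for a lossless aligner; the convention is
  60 (unique best), 3 (2–9 co-optimal), 0 (≥ 10).
- Error rates resolve to `k = floor(rate × read length)`, capped at 13
  (2% of 151 bp → 3; 8% of 150 bp → 12).
- Proper pairs: convergent orientation (leftmost mate forward), fragment
  length measured outer-to-outer, accepted within `μ ± 6σ`. "Smallest
  edit distance across both reads" is implemented as minimizing
  `d1 + d2` (sum rather than max — the natural total-cost reading).
  Without a proper pair the mates are reported unpaired (pair flags kept,
  proper-pair bit unset).
- The fragment model is estimated from the first 1000 pairs whose mates
  both have a unique best alignment in convergent orientation; with fewer
  than 50 such pairs it falls back to documented defaults
  (μ = 500, σ = 100) and logs the fallback.

## Synthetic data

The generator states a world and sticks to it: uniform-composition
genomes at a requested GC fraction; reads planted at uniform positions
and strands with independent per-position errors, defaulting to 1%
substitutions and 0.1% each insertions/deletions (Illumina-like); paired
mode plants convergent mates at Gaussian fragment lengths (default
400 ± 30 bp). The truth table records the origin window, strand, planted
operations and the DP-verified distance (adjacent planted operations can
cancel, so the verified distance is authoritative). What it does *not*
emulate: coverage bias, quality-correlated errors, repeats beyond what a
random sequence contains, or structural variation — so a green
planted-read test establishes losslessness of the search machinery on
near-uniform texts, not robustness to pathological repeat structure
(which the small-text oracle tests probe more directly, since short
random texts are repeat-dense relative to read length).

## Numerical and degenerate-input choices

- Band half-width is fixed at `k` for the whole alignment — the simplest
  sound choice.
- Dynamic partitioning is greedy: starting from uniform cuts, the part
  with the most exact matches is widened one column at a time at the
  expense of its smaller neighbour, budget `2p` moves, stopping when
  max/min counts are within a factor 4 or no move strictly reduces the
  maximum. Patterns whose parts count zero exact matches keep uniform
  cuts. Partitioning and scheme selection are pure performance knobs;
  invariance of the output is a tested property.
- Scheme selection minimizes the sum over searches of the exact-match
  count of the search's first part; ties go to the earlier candidate.
- Empty ranges are results, not errors; unmapped reads yield a FLAG 4
  record. A pattern not longer than `k`, or shorter than the part count,
  is rejected.
- Index serialization stores the sanitized text and rebuilds the derived
  structures deterministically on load, guarded by a format-version tag
  and a SHA-256 checksum.

## Known limitations

- Pure-Python/numpy throughput (~10 ms per 100 bp read at `k = 3` against
  a 100 kb reference) is desk-scale: suitable for validation, small
  references and method study, not for whole-genome production runs.
- No multithreading, no run-length-compressed index backend, no BAM/CRAM
  or PAF output, no spliced alignment.
- MAPQ and primary-selection tie-breaks are documented conventions, not
  claims of compatibility with any other tool.
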