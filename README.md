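# lossmap

Lossless short-read alignment with search schemes over a bidirectional
FM-index.

Most popular read aligners are *lossy*: they report one or a few
high-scoring placements per read. For applications where a read must be
attributed to **every** reference it could plausibly come from — HLA
typing, bacterial strain identification, metagenomic classification,
pan-genome analysis — that is not enough. `lossmap` is a *lossless*
aligner: given a maximum edit distance `k` (substitutions + indels, up to
`k = 13`), it reports

- **all mode** — every occurrence of the read within distance `k`, and
- **all-best mode** — every occurrence at the smallest achievable
  distance (the read's *stratum*), found by trying `k = 0, 1, …`.

Paired-end input is resolved to all optimal *proper pairs*: convergently
oriented mates whose outer fragment length lies within six standard
deviations of the fragment-size mean, inferred from the data; optimality
is the smallest `d1 + d2`. Output is SAM, with `NM` carrying the edit
distance and co-optimal placements emitted as separate records.

## How it works

A pattern `P` is split into `p` parts `P1…Pp`. A **search scheme** for
budget `k` is a set of searches `S = (π, L, U)` — a part-processing order
`π` (each next part adjacent to the already-processed block, so the
bidirectional index can always extend at one end) plus non-decreasing
cumulative lower/upper error bounds `L, U` — that together *cover* every
distribution of ≤ `k` errors over the parts. Coverage is what makes the
matcher provably lossless; it is checked here by exhaustive enumeration of
all error vectors. Bundled schemes are the pigeonhole family (`p = k + 1`,
one exact part per search); optimized schemes can be loaded from plain
text files.

Each search walks a **bidirectional FM-index** (BWT of the text and of its
reverse, kept in sync) character by character, maintaining a banded
edit-distance column per direction computed **bit-parallel** (Myers-style
delta vectors; a full-width row is exactly equivalent to the band because
any cell `(i, j)` with `|i − j| > k` has value `> k`). Per pattern the
partition may be rebalanced by exact-match counts (**dynamic
partitioning**) and the cheapest candidate scheme chosen (**dynamic
selection**); neither affects the reported occurrences, only runtime.
When fewer than 4 candidate positions remain, the matcher **switches to
in-text verification**, finishing the alignment directly against the
located text slice. Redundant overlapping variants (a leading/trailing gap
traded for a substitution) are clustered to representatives.

## Worked example

```
$ python - <<'PY'
from lossmap import build_index, map_single, ReadRecord
from lossmap.synthetic import random_genome, sample_reads

genome = random_genome(50_000, n_records=2, seed=1)   # two ~25 kb records
index = build_index(genome)
reads, truth = sample_reads(genome, 5, read_length=100, seed=7)
for read, t in zip(reads, truth):
    rec = map_single(read, 3, "all-best", index)[0]
    print(read.name, rec.rname, rec.pos, rec.cigar, "NM=%d" % rec.tags["NM"],
          "planted:", t.record, t.start + 1, "d=%d" % t.distance)
PY
r000000 seq2 17030 100M NM=3 planted: seq2 17030 d=3
r000001 seq2 16983 100M NM=1 planted: seq2 16983 d=1
r000002 seq2 22416 100M NM=0 planted: seq2 22416 d=0
r000003 seq2 21258 100M NM=0 planted: seq2 21258 d=0
r000004 seq2 5435 100M NM=0 planted: seq2 5435 d=0
```

Each line shows the primary SAM placement (reference record, 1-based
position, CIGAR, edit distance) against the planted origin; a lossless run
recovers every planted locus whose true distance is within the budget.

The same pipeline from the shell:

```
lossmap index --ref ref.fa --out idx
lossmap align --index idx --reads r1.fq --reads2 r2.fq \
        --error-rate 0.02 --mode all-best --out out.sam
```

`--error-rate 0.02` on 151 bp reads resolves to `k = 3`. A JSON run
summary (reads in/aligned, strata histogram) is written next to the SAM.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates a synthetic genome and read set from the seed, builds the
index, runs single-end all-best and paired-end alignment end to end,
prints a run summary, and writes the results file. The correctness
properties themselves (oracle equality, scheme coverage, strata,
configuration invariance, planted-read recovery, SAM compliance) live in
`tests/test_acceptance.py`.
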