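"""Deterministic synthetic genomes and reads with known ground truth.

Every component of the aligner is testable offline: the generator plants
reads (optionally convergent mate pairs at Gaussian fragment lengths) at
known loci with independent per-position substitution/insertion/deletion
errors, and records for each read its origin, strand, the planted edit
operations and the DP-verified edit distance to the origin window (adjacent
planted operations can cancel, so the verified distance may be smaller than
the operation count).

Default rates emulate desk-scale Illumina-like data: 1% substitutions and
0.1% each of insertions and deletions, 100 bp reads, 400 +/- 30 bp
fragments for paired mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .mapping import ReadRecord

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ReadTruth:
    """Ground truth for one planted read."""

    name: str
    mate: int            # 0 single-end, 1/2 for pairs
    record: str          # reference record name
    start: int           # 0-based origin start within the record
    end: int             # origin end (exclusive)
    strand: str
    operations: str      # planted ops, e.g. "S12;I30;D31" (read coordinates)
    distance: int        # DP-verified edit distance read vs origin window
    fragment: int = 0    # planted outer fragment length (pairs only)


def random_genome(length: int, n_records: int = 1, gc: float = 0.5,
                  seed: int = 0) -> list[tuple[str, str]]:
    """Random genome records with the requested GC fraction.

    Returns ``[(name, sequence), ...]``; reproducible for a fixed seed.
    """
    if length < n_records:
        raise ValueError("length must be at least the number of records")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be a fraction in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    sizes = [length // n_records] * n_records
    sizes[-1] += length - sum(sizes)
    out = []
    for i, size in enumerate(sizes):
        seq = "".join(rng.choice(_BASES, size=size, p=p))
        out.append((f"seq{i + 1}", seq))
    return out


def _mutate(window: str, rng: np.random.Generator, sub_rate: float,
            ins_rate: float, del_rate: float, read_length: int
            ) -> tuple[str, int, str]:
    """Copy a genome window into a read with planted errors.

    Returns (read, consumed_reference_length, operations string).
    """
    read: list[str] = []
    ops: list[str] = []
    i = 0
    while len(read) < read_length and i < len(window):
        r = rng.random()
        if r < del_rate:
            ops.append(f"D{len(read)}")
            i += 1
        elif r < del_rate + ins_rate:
            read.append(str(rng.choice(_BASES)))
            ops.append(f"I{len(read) - 1}")
        elif r < del_rate + ins_rate + sub_rate:
            orig = window[i]
            choices = [b for b in "ACGT" if b != orig]
            read.append(str(rng.choice(choices)))
            ops.append(f"S{len(read) - 1}")
            i += 1
        else:
            read.append(window[i])
            i += 1
    return "".join(read), i, ";".join(ops)


def _edit_distance(a: str, b: str) -> int:
    """Plain DP distance used to verify the planted error count."""
    prev = np.arange(len(b) + 1)
    for i, ca in enumerate(a, 1):
        cur = np.empty(len(b) + 1, dtype=np.int64)
        cur[0] = i
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j - 1] + (ca != cb), prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return int(prev[-1])


_REVCOMP = str.maketrans("ACGT", "TGCA")


def sample_reads(genome: Sequence[tuple[str, str]], n_reads: int,
                 read_length: int = 100, sub_rate: float = 0.01,
                 ins_rate: float = 0.001, del_rate: float = 0.001,
                 paired: tuple[float, float] | None = None, seed: int = 0,
                 ) -> tuple[list[ReadRecord], list[ReadTruth]]:
    """Sample reads (or convergent mate pairs) with planted errors.

    ``paired`` is ``(fragment_mean, fragment_sd)``; in paired mode
    ``n_reads`` counts pairs and mates are interleaved /1, /2 in the output.
    Expected errors per read must stay within the k = 13 ceiling.
    """
    if (sub_rate + ins_rate + del_rate) * read_length > 13:
        raise ValueError("expected planted errors exceed the k = 13 ceiling")
    if any(r < 0 for r in (sub_rate, ins_rate, del_rate)):
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    names = [name for name, _ in genome]
    seqs = dict(genome)
    weights = np.array([len(s) for _, s in genome], dtype=float)
    weights /= weights.sum()
    margin = read_length + max(4, int(0.1 * read_length))

    reads: list[ReadRecord] = []
    truth: list[ReadTruth] = []

    def plant(name: str, rec: str, offset: int, strand: str, mate: int,
              fragment: int = 0) -> tuple[int, int]:
        seq = seqs[rec]
        window = seq[offset: offset + margin]
        read, span, ops = _mutate(window, rng, sub_rate, ins_rate, del_rate,
                                  read_length)
        if len(read) < read_length:
            raise ValueError("read longer than the available genome window")
        origin = seq[offset: offset + span]
        dist = _edit_distance(read, origin)
        if strand == "-":
            read = read.translate(_REVCOMP)[::-1]
        reads.append(ReadRecord(name, read, "I" * len(read), mate))
        truth.append(ReadTruth(name, mate, rec, offset, offset + span,
                               strand, ops, dist, fragment))
        return offset, offset + span

    for i in range(n_reads):
        name = f"r{i:06d}"
        rec = names[int(rng.choice(len(names), p=weights))]
        seq = seqs[rec]
        if paired is None:
            if len(seq) < margin:
                raise ValueError("read longer than genome record")
            offset = int(rng.integers(0, len(seq) - margin + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            plant(name, rec, offset, strand, 0)
        else:
            mean, sd = paired
            frag = int(round(rng.normal(mean, sd)))
            frag = max(frag, read_length + 8)
            if len(seq) < frag + margin - read_length:
                raise ValueError("fragment longer than genome record")
            offset = int(rng.integers(0, len(seq) - frag - (margin - read_length) + 1))
            # mate 1 from the left (forward), mate 2 from the right (reverse);
            # which physical mate is /1 alternates uniformly
            left_is_first = rng.random() < 0.5
            right_off = offset + frag - read_length
            if left_is_first:
                plant(name, rec, offset, "+", 1, frag)
                plant(name, rec, right_off, "-", 2, frag)
            else:
                plant(name, rec, right_off, "-", 1, frag)
                plant(name, rec, offset, "+", 2, frag)
    return reads, truth


def truth_to_tsv(truth: Sequence[ReadTruth]) -> str:
    """Sidecar tab-separated truth table keyed by read name."""
    lines = ["#name\tmate\trecord\tstart\tend\tstrand\toperations\tdistance"
             "\tfragment"]
    for t in truth:
        lines.append(f"{t.name}\t{t.mate}\t{t.record}\t{t.start}\t{t.end}\t"
                     f"{t.strand}\t{t.operations or '.'}\t{t.distance}\t"
                     f"{t.fragment}")
    return "\n".join(lines) + "\n"
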