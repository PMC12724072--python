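"""Readers and writers for the formats the aligner touches.

FASTA/FASTQ parsing is delegated to Biopython (gzip transparently detected
by magic bytes, not extension), SAM writing to pysam, and the index is
serialized as a directory of numpy arrays plus a checksummed JSON manifest.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
import pysam
from Bio import SeqIO

from . import __version__
from .index import FmIndex, RecordInfo
from .mapping import ReadRecord, SamRecord

GZIP_MAGIC = b"\x1f\x8b"
INDEX_FORMAT_VERSION = 1
_MANIFEST = "manifest.json"


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> Iterator[ReadRecord]:
    """Lazily yield FASTA records, sequences upper-cased."""
    with _open_text(path) as fh:
        for i, rec in enumerate(SeqIO.parse(fh, "fasta")):
            seq = str(rec.seq).upper()
            if not seq:
                raise ValueError(f"{path}: record {i + 1} ({rec.id}) is empty")
            yield ReadRecord(rec.id, seq)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Lazily yield FASTQ records; framing/length errors carry the record
    number."""
    with _open_text(path) as fh:
        parser = SeqIO.parse(fh, "fastq")
        i = 0
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"{path}: record {i + 1}: {exc}") from None
            i += 1
            quals = "".join(chr(q + 33)
                            for q in rec.letter_annotations["phred_quality"])
            yield ReadRecord(rec.id, str(rec.seq).upper(), quals)


def read_reads(path: str | Path) -> Iterator[ReadRecord]:
    """Dispatch on the leading character ('>' FASTA, '@' FASTQ)."""
    with _open_text(path) as fh:
        first = fh.read(1)
    if first == ">":
        return read_fasta(path)
    if first == "@":
        return read_fastq(path)
    raise ValueError(f"{path}: neither FASTA nor FASTQ")


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = read.qualities or "I" * len(read.sequence)
            suffix = f"/{read.mate}" if read.mate else ""
            fh.write(f"@{read.name}{suffix}\n{read.sequence}\n+\n{qual}\n")


# -- SAM -------------------------------------------------------------------


def sam_header(references: Iterable[RecordInfo],
               command_line: str | None = None) -> dict:
    head = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": r.name, "LN": r.length} for r in references],
        "PG": [{"ID": "lossmap", "PN": "lossmap", "VN": __version__,
                **({"CL": command_line} if command_line else {})}],
    }
    return head


def write_sam(records: Iterable[SamRecord], header: dict, path: str | Path
              ) -> None:
    """Write SAM through pysam (guarantees spec-conformant field order)."""
    header = pysam.AlignmentHeader.from_dict(header)
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(header)
            a.query_name = rec.qname
            a.flag = rec.flag
            if rec.rname != "*":
                a.reference_id = header.get_tid(rec.rname)
                if a.reference_id < 0:
                    raise ValueError(f"unknown reference {rec.rname!r}")
                a.reference_start = rec.pos - 1
            a.mapping_quality = rec.mapq
            if rec.cigar != "*":
                a.cigarstring = rec.cigar
            if rec.rnext != "*":
                a.next_reference_id = (a.reference_id if rec.rnext == "="
                                       else header.get_tid(rec.rnext))
                a.next_reference_start = rec.pnext - 1
            a.template_length = rec.tlen
            if rec.seq != "*":
                a.query_sequence = rec.seq
                if rec.qual != "*":
                    a.query_qualities = pysam.qualitystring_to_array(rec.qual)
            for tag, value in rec.tags.items():
                a.set_tag(tag, value)
            out.write(a)


# -- index serialization ---------------------------------------------------

_ARRAYS = ("codes",)


def save_index(index: FmIndex, directory: str | Path) -> None:
    """Versioned on-disk layout: numpy arrays plus a checksummed manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    digest = hashlib.sha256()
    for name in _ARRAYS:
        arr = getattr(index, name)
        np.save(directory / f"{name}.npy", arr)
        digest.update((directory / f"{name}.npy").read_bytes())
    manifest = {
        "format_version": INDEX_FORMAT_VERSION,
        "tool_version": __version__,
        "sa_sampling": index.sa_sampling,
        "n": index.n,
        "records": [[r.name, r.start, r.length] for r in index.records],
        "sha256": digest.hexdigest(),
    }
    (directory / _MANIFEST).write_text(json.dumps(manifest, indent=1))


def load_index(directory: str | Path) -> FmIndex:
    """Load a serialized index; validates version tag and checksum.

    The rank/BWT structures are rebuilt deterministically from the stored
    sanitized text, so a load answers every query exactly like the original.
    """
    directory = Path(directory)
    manifest_path = directory / _MANIFEST
    if not manifest_path.exists():
        raise FileNotFoundError(f"{directory}: not an index (no {_MANIFEST})")
    manifest = json.loads(manifest_path.read_text())
    version = manifest.get("format_version")
    if version != INDEX_FORMAT_VERSION:
        raise ValueError(
            f"{directory}: index format version {version} is not supported "
            f"(expected {INDEX_FORMAT_VERSION})")
    digest = hashlib.sha256()
    for name in _ARRAYS:
        digest.update((directory / f"{name}.npy").read_bytes())
    if digest.hexdigest() != manifest["sha256"]:
        raise ValueError(f"{directory}: checksum mismatch, index corrupt")
    codes = np.load(directory / "codes.npy")
    records = [RecordInfo(n, s, l) for n, s, l in manifest["records"]]
    return FmIndex(codes, records, manifest["sa_sampling"])
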