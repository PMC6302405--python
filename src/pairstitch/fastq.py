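"""FASTQ records, paired iteration, and sequence utilities.

Reads and writes 4-line FASTQ (plain or gzip, detected by magic bytes),
decodes Phred qualities (ASCII - offset, default 33), and enforces the
pairing contract that R1/R2 read names agree after stripping a trailing
mate suffix ("/1", "/2", ".1", ".2") or whitespace comment.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import numpy as np

__all__ = [
    "FastqRecord",
    "ReadPair",
    "FastqFormatError",
    "PairingError",
    "EncodingError",
    "read_fastq",
    "read_fastq_pairs",
    "write_fastq",
    "reverse_complement",
]

MAX_QUAL = 93

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")


class FastqFormatError(ValueError):
    """Malformed FASTQ record (wrong line count, marker, or length)."""


class PairingError(ValueError):
    """R1/R2 files disagree on read names or record counts."""


class EncodingError(ValueError):
    """Quality character outside the representable Phred range."""


@dataclass(eq=False)
class FastqRecord:
    """One sequencing read: identifier, bases, per-base Phred qualities.

    ``id`` is the text after '@' (its first whitespace-delimited token is
    the read name); ``seq`` is uppercase over {A,C,G,T,N}; ``quals`` is an
    integer array in [0, 93], one entry per base.
    """

    id: str
    seq: str
    quals: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.seq) != len(self.quals):
            raise FastqFormatError(
                f"record {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.quals)}"
            )

    @property
    def name(self) -> str:
        """Read name: first whitespace-delimited token of the id."""
        return self.id.split()[0] if self.id else ""

    def __len__(self) -> int:
        return len(self.seq)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FastqRecord):
            return NotImplemented
        return (
            self.id == other.id
            and self.seq == other.seq
            and np.array_equal(self.quals, other.quals)
        )

    def qual_string(self, offset: int = 33) -> str:
        if self.quals.size and int(self.quals.max()) > MAX_QUAL:
            raise EncodingError(
                f"record {self.id!r}: quality above {MAX_QUAL} cannot be encoded"
            )
        if self.quals.size and int(self.quals.min()) < 0:
            raise EncodingError(f"record {self.id!r}: negative quality score")
        return "".join(chr(int(q) + offset) for q in self.quals)


def _strip_mate_suffix(name: str) -> str:
    if len(name) > 2 and name[-2] in "/." and name[-1] in "12":
        return name[:-2]
    return name


@dataclass(frozen=True)
class ReadPair:
    """A read pair (R1, R2) whose names match after mate-suffix stripping."""

    r1: FastqRecord
    r2: FastqRecord

    def __post_init__(self) -> None:
        n1 = _strip_mate_suffix(self.r1.name)
        n2 = _strip_mate_suffix(self.r2.name)
        if n1 != n2:
            raise PairingError(f"paired read names differ: {n1!r} vs {n2!r}")


def _open_maybe_gzip(path: str | os.PathLike, mode: str = "rt") -> IO[str]:
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_records(
    handle: IO[str], offset: int, path: str
) -> Iterator[FastqRecord]:
    lineno = 0
    while True:
        header = handle.readline()
        if not header:
            return
        lineno += 1
        header = header.rstrip("\n")
        if not header.startswith("@"):
            raise FastqFormatError(
                f"{path}:{lineno}: expected '@' header, got {header[:20]!r}"
            )
        seq = handle.readline()
        plus = handle.readline()
        qual = handle.readline()
        if not qual:
            raise FastqFormatError(
                f"{path}:{lineno}: truncated record {header[:40]!r}"
            )
        lineno += 3
        seq = seq.rstrip("\n").upper()
        qual = qual.rstrip("\n")
        if not plus.startswith("+"):
            raise FastqFormatError(f"{path}:{lineno - 1}: missing '+' separator")
        if len(seq) != len(qual):
            raise FastqFormatError(
                f"{path}:{lineno}: sequence/quality length mismatch"
            )
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FastqFormatError(
                f"{path}:{lineno - 2}: invalid base(s) {sorted(bad)}"
            )
        quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(
            np.int16
        ) - offset
        if quals.size and int(quals.min()) < 0:
            raise EncodingError(
                f"{path}:{lineno}: quality character below offset {offset}"
            )
        yield FastqRecord(id=header[1:], seq=seq, quals=quals)


def read_fastq(path: str | os.PathLike, offset: int = 33) -> Iterator[FastqRecord]:
    """Yield records from one FASTQ file (gzip detected transparently)."""
    with _open_maybe_gzip(path) as handle:
        yield from _parse_records(handle, offset, str(path))


def read_fastq_pairs(
    path1: str | os.PathLike,
    path2: str | os.PathLike | None = None,
    offset: int = 33,
    interleaved: bool = False,
) -> Iterator[ReadPair]:
    """Yield ReadPairs from two parallel FASTQ files (or one interleaved).

    Raises PairingError on unequal record counts or mismatched names, and
    FastqFormatError/EncodingError (with file and line) on malformed input.
    """
    if interleaved:
        if path2 is not None:
            raise ValueError("interleaved input takes a single file")
        stream = read_fastq(path1, offset)
        for r1 in stream:
            r2 = next(stream, None)
            if r2 is None:
                raise PairingError(f"{path1}: odd record count in interleaved file")
            yield ReadPair(r1, r2)
        return
    if path2 is None:
        raise ValueError("two files required unless interleaved=True")
    it1 = read_fastq(path1, offset)
    it2 = read_fastq(path2, offset)
    for r1 in it1:
        r2 = next(it2, None)
        if r2 is None:
            raise PairingError(f"{path2} has fewer records than {path1}")
        yield ReadPair(r1, r2)
    if next(it2, None) is not None:
        raise PairingError(f"{path2} has more records than {path1}")


def write_fastq(
    records: Iterable[FastqRecord],
    path: str | os.PathLike,
    offset: int = 33,
) -> int:
    """Write records as 4-line FASTQ; gzip if path ends in '.gz'.

    Returns the number of records written. Round-trips with read_fastq.
    """
    n = 0
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as out:
        for rec in records:
            out.write(f"@{rec.id}\n{rec.seq}\n+\n{rec.qual_string(offset)}\n")
            n += 1
    return n


def format_fastq(rec: FastqRecord, offset: int = 33) -> str:
    return f"@{rec.id}\n{rec.seq}\n+\n{rec.qual_string(offset)}\n"


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N} (N maps to N)."""
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"cannot complement non-ACGTN base(s): {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]
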