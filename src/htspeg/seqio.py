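"""Sequence records, FASTA/FASTQ I/O and coordinate primitives.

All coordinates in this package are 0-based, half-open intervals on the
forward strand of the named sequence; conversion to 1-based happens only
when AGP is written.  Sequences are plain upper-case strings over
``{A, C, G, T, N}``; qualities are kept as Sanger(+33)-encoded strings so
that FASTQ round-trips are lossless.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class FormatError(ValueError):
    """A sequence file violated its format; the message names the line."""


def revcomp(bases: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N} (case kept).

    ``revcomp`` is an involution and preserves length.
    """
    if not set(bases.upper()) <= VALID_BASES:
        bad = sorted(set(bases.upper()) - VALID_BASES)
        raise ValueError(f"non-DNA characters in sequence: {bad}")
    return bases.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, slots=True)
class SeqRecord:
    """One named sequence with optional per-base qualities."""

    id: str
    bases: str
    quals: str | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id must be non-empty without whitespace: {self.id!r}")
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise ValueError(
                f"{self.id}: quality length {len(self.quals)} != sequence length {len(self.bases)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """0-based half-open interval ``[start, end)`` on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def _open(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _check_bases(bases: str, path: str | Path, lineno: int) -> str:
    bases = bases.upper()
    if not set(bases) <= VALID_BASES:
        bad = sorted(set(bases) - VALID_BASES)
        raise FormatError(f"{path}:{lineno}: non-IUPAC characters {bad}")
    return bases


def read_fasta(path: str | Path) -> Iterator[SeqRecord]:
    """Stream records from a (possibly multi-line, possibly gzipped) FASTA file."""
    rec_id: str | None = None
    parts: list[str] = []
    header_line = 0
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if rec_id is not None:
                    yield _finish_fasta(rec_id, parts, path, header_line)
                rec_id = line[1:].split()[0] if len(line) > 1 and line[1:].split() else ""
                if not rec_id:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                header_line = lineno
                parts = []
            elif rec_id is None:
                raise FormatError(f"{path}:{lineno}: sequence data before any header")
            else:
                parts.append(_check_bases(line, path, lineno))
        if rec_id is not None:
            yield _finish_fasta(rec_id, parts, path, header_line)


def _finish_fasta(rec_id: str, parts: list[str], path: str | Path, lineno: int) -> SeqRecord:
    bases = "".join(parts)
    if not bases:
        raise FormatError(f"{path}:{lineno}: record {rec_id!r} has no sequence")
    return SeqRecord(rec_id, bases)


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 80) -> int:
    """Write records as FASTA; returns the number of records written."""
    n = 0
    with _open(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.bases), width):
                fh.write(rec.bases[i : i + width] + "\n")
            n += 1
    return n


def read_fastq(path: str | Path) -> Iterator[SeqRecord]:
    """Stream 4-line FASTQ records with Sanger(+33) qualities."""
    with _open(path) as fh:
        lineno = 0
        while True:
            head = fh.readline()
            if not head:
                return
            lineno += 1
            head = head.rstrip("\n")
            if not head.startswith("@") or len(head) < 2:
                raise FormatError(f"{path}:{lineno}: expected '@' header, got {head!r}")
            rec_id = head[1:].split()[0]
            lines = [fh.readline() for _ in range(3)]
            if any(not ln for ln in lines):
                raise FormatError(f"{path}:{lineno}: truncated FASTQ record {rec_id!r}")
            seq, plus, qual = (ln.rstrip("\n") for ln in lines)
            if not plus.startswith("+"):
                raise FormatError(f"{path}:{lineno + 2}: expected '+' separator")
            seq = _check_bases(seq, path, lineno + 1)
            if len(qual) != len(seq):
                raise FormatError(
                    f"{path}:{lineno + 3}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            lineno += 3
            yield SeqRecord(rec_id, seq, qual)


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> int:
    """Write records as 4-line FASTQ; records lacking qualities get Q30."""
    n = 0
    with _open(path, "wt") as fh:
        for rec in records:
            quals = rec.quals if rec.quals is not None else "?" * len(rec.bases)
            fh.write(f"@{rec.id}\n{rec.bases}\n+\n{quals}\n")
            n += 1
    return n
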