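"""FASTA/FASTQ reading and writing, transparently gzip-compressed.

Records are never rewritten on the way through: sequence and quality strings
are kept byte-for-byte as parsed (no case folding, no stripping of ambiguous
bases).  Any cleaning or skipping happens downstream at k-mer extraction,
where it cannot alter the user's data files.

FASTA parsing is delegated to Biopython's SimpleFastaParser.  FASTQ is
restricted to the unambiguous 4-line dialect and parsed here directly, so
parse errors can name the offending record and line number and multi-line
FASTQ is rejected loudly rather than guessed at.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from typing import IO, Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import ConfigurationError, ParseError

__all__ = ["SequenceRecord", "read_records", "write_records"]

_FASTA_WRAP = 80


@dataclass
class SequenceRecord:
    """One read: identifier, optional description, sequence, optional quality."""

    id: str
    sequence: str
    quality: str | None = None
    description: str | None = None

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ParseError(
                f"record {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )

    @property
    def header(self) -> str:
        return f"{self.id} {self.description}" if self.description else self.id


def _split_title(title: str) -> tuple[str, str | None]:
    parts = title.split(None, 1)
    if not parts:
        return "", None
    return parts[0], (parts[1] if len(parts) > 1 else None)


def _open_read(path) -> IO[str]:
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


class _GzTextWriter(io.TextIOWrapper):
    """Gzip text writer with fixed mtime and no embedded filename, so
    identical record streams always produce identical bytes."""

    def __init__(self, path):
        self._raw = open(path, "wb")
        super().__init__(
            gzip.GzipFile(filename="", mode="wb", fileobj=self._raw, mtime=0)
        )

    def close(self) -> None:
        try:
            super().close()
        finally:
            self._raw.close()


def _open_write(path) -> IO[str]:
    if str(path).endswith(".gz"):
        return _GzTextWriter(path)
    return open(path, "wt")


def _iter_fastq(fh: IO[str], path) -> Iterator[SequenceRecord]:
    lineno = 0
    while True:
        header = fh.readline()
        if not header:
            return
        lineno += 1
        header = header.rstrip("\n")
        if not header.startswith("@"):
            raise ParseError(
                f"{path}:{lineno}: expected '@' header, got {header[:30]!r} "
                "(multi-line FASTQ is not supported)"
            )
        seq = fh.readline().rstrip("\n")
        plus = fh.readline().rstrip("\n")
        qual = fh.readline().rstrip("\n")
        if not qual and not plus:
            raise ParseError(f"{path}:{lineno}: truncated FASTQ record {header[1:]!r}")
        lineno += 3
        if not plus.startswith("+"):
            raise ParseError(
                f"{path}:{lineno - 1}: expected '+' separator in record "
                f"{header[1:]!r} (multi-line FASTQ is not supported)"
            )
        rid, desc = _split_title(header[1:])
        if len(qual) != len(seq):
            raise ParseError(
                f"{path}:{lineno}: record {rid!r}: quality length {len(qual)} "
                f"!= sequence length {len(seq)}"
            )
        yield SequenceRecord(id=rid, sequence=seq, quality=qual, description=desc)


def read_records(path) -> Iterator[SequenceRecord]:
    """Yield records from a FASTA or FASTQ file (plain or gzip) in file order.

    The format is auto-detected from the first byte ('>' FASTA, '@' FASTQ);
    an empty file yields an empty stream.
    """
    fh = _open_read(path)
    try:
        first = fh.read(1)
        if first == "":
            return
        fh.seek(0)
        if first == ">":
            for title, seq in SimpleFastaParser(fh):
                rid, desc = _split_title(title)
                yield SequenceRecord(id=rid, sequence=seq, description=desc)
        elif first == "@":
            yield from _iter_fastq(fh, path)
        else:
            raise ParseError(
                f"{path}: unrecognized format (first byte {first!r}; expected '>' or '@')"
            )
    finally:
        fh.close()


def _infer_format(path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fa", ".fasta", ".fna")):
        return "fasta"
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    raise ConfigurationError(
        f"cannot infer sequence format from {path!r}; pass format='fasta' or 'fastq'"
    )


def write_records(records: Iterable[SequenceRecord], path, format: str | None = None) -> int:
    """Write records in order; returns the count written.

    FASTA output wraps sequence lines at 80 columns; FASTQ output demands a
    quality string on every record.  A ``.gz`` suffix compresses the output.
    """
    fmt = format or _infer_format(path)
    if fmt not in ("fasta", "fastq"):
        raise ConfigurationError(f"unknown format {fmt!r}")
    fh = _open_write(path)
    n = 0
    try:
        for rec in records:
            if fmt == "fastq":
                if rec.quality is None:
                    raise ConfigurationError(
                        f"record {rec.id!r} has no quality string; cannot write FASTQ"
                    )
                fh.write(f"@{rec.header}\n{rec.sequence}\n+\n{rec.quality}\n")
            else:
                fh.write(f">{rec.header}\n")
                seq = rec.sequence
                for i in range(0, max(1, len(seq)), _FASTA_WRAP):
                    fh.write(seq[i : i + _FASTA_WRAP] + "\n")
            n += 1
    finally:
        fh.close()
    return n
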