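"""Abundance-based error trimming and simple quality filtering.

A sequencing error creates up to k novel k-mers that almost never recur in
the data set, so a read's k-mer abundance profile drops sharply at the first
error.  ``trim_low_abundance`` exploits this: after the whole data set has
been counted into a sketch, each read is truncated at its first k-mer whose
abundance falls below a cutoff.  This is a two-pass design — count
everything, then trim — and reads are truncated, never split.

``quality_filter`` is a deliberately minimal quality-control stage (mean
Phred score and minimum length) so that a complete pre-filtering pipeline
can run self-contained; it performs no sequence modification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .countmin import CountMinSketch
from .errors import ConfigurationError
from .seqio import SequenceRecord

__all__ = [
    "TrimParams",
    "FilterReport",
    "trim_low_abundance",
    "filter_abund",
    "quality_filter",
]


@dataclass(frozen=True)
class TrimParams:
    """Abundance cutoff and minimum surviving read length.

    ``min_length=None`` defaults to the sketch's k at call time (a read
    shorter than k carries no k-mer evidence at all).
    """

    min_count: int = 2
    min_length: int | None = None

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise ConfigurationError(f"min_count must be >= 1, got {self.min_count}")


@dataclass
class FilterReport:
    n_seen: int = 0
    n_trimmed: int = 0
    n_discarded: int = 0


def _resolve_min_length(params: TrimParams, k: int) -> int:
    min_length = params.min_length if params.min_length is not None else k
    if min_length < k:
        raise ConfigurationError(f"min_length {min_length} must be >= k ({k})")
    return min_length


def trim_low_abundance(
    read: SequenceRecord, sketch: CountMinSketch, params: TrimParams
) -> SequenceRecord | None:
    """Truncate ``read`` at its first low-abundance k-mer.

    Let i be the smallest k-mer start position whose sketch count is below
    ``params.min_count`` (windows containing ambiguous bases carry no count
    and are not considered).  The read is returned unchanged if no such i
    exists, truncated to its first ``i + k - 1`` bases (quality truncated
    identically) otherwise, or ``None`` if the surviving length falls below
    ``min_length``.
    """
    k = sketch.spec.k
    min_length = _resolve_min_length(params, k)
    if len(read.sequence) < k:
        return None  # shorter than k: below min_length by construction
    positions, counts = sketch.counts_for_sequence(read.sequence)
    low = counts < params.min_count
    if not low.any():
        return read
    i = int(positions[low.argmax()])
    keep = i + k - 1
    if keep < min_length:
        return None
    return SequenceRecord(
        id=read.id,
        sequence=read.sequence[:keep],
        quality=read.quality[:keep] if read.quality is not None else None,
        description=read.description,
    )


def filter_abund(
    reads: Iterable[SequenceRecord], sketch: CountMinSketch, params: TrimParams
) -> tuple[list[SequenceRecord], FilterReport]:
    """Apply :func:`trim_low_abundance` to every read, preserving order."""
    report = FilterReport()
    kept: list[SequenceRecord] = []
    for rec in reads:
        report.n_seen += 1
        out = trim_low_abundance(rec, sketch, params)
        if out is None:
            report.n_discarded += 1
        else:
            if out.sequence != rec.sequence:
                report.n_trimmed += 1
            kept.append(out)
    return kept, report


def mean_phred(quality: str) -> float:
    """Mean Phred score of a Phred+33 quality string."""
    if not quality:
        return 0.0
    return sum(ord(c) - 33 for c in quality) / len(quality)


def quality_filter(
    reads: Iterable[SequenceRecord],
    min_mean_q: float | None = None,
    min_len: int = 1,
) -> list[SequenceRecord]:
    """Drop reads with mean Phred quality < ``min_mean_q`` or length < ``min_len``.

    Quality strings are assumed Phred+33.  Records without qualities (FASTA)
    are rejected when a quality threshold is requested, since the check
    cannot be performed.  Sequences are never modified.
    """
    kept: list[SequenceRecord] = []
    for rec in reads:
        if len(rec.sequence) < min_len:
            continue
        if min_mean_q is not None:
            if rec.quality is None:
                raise ConfigurationError(
                    f"record {rec.id!r} has no quality string; "
                    "cannot apply a mean-quality threshold to FASTA input"
                )
            if mean_phred(rec.quality) < min_mean_q:
                continue
        kept.append(rec)
    return kept
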