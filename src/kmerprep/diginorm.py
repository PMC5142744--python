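"""Digital normalization: streaming, lossy down-sampling of read sets.

The algorithm makes one pass over the reads.  For each read, the median
abundance of its k-mers is looked up in a CountMin sketch that reflects only
the reads *kept so far*.  If that median is below the coverage cutoff C the
read is emitted unchanged and its k-mers are counted in; otherwise the read
is discarded and the sketch is untouched.  The effect is that each genomic
locus accumulates roughly C-fold coverage and the redundant remainder of the
data set is dropped, in fixed memory and a single pass.

Two choices fixed here (and relied on by the invariants):

* counts are queried before any update, and k-mers are added only for kept
  reads — this makes a second pass over the output keep everything
  (idempotence), since each kept read replays the sketch state it saw;
* the keep condition is strictly ``median < C``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .countmin import COUNTER_CAP, CountMinSketch
from .errors import ConfigurationError
from .kmer_core import HashFamily, KmerSpec, sequence_codes

__all__ = ["DiginormParams", "DiginormReport", "normalize_by_median", "estimate_retained_coverage"]

DEFAULT_TABLE_SIZE = 1_000_000
DEFAULT_N_TABLES = 4


@dataclass(frozen=True)
class DiginormParams:
    """Coverage cutoff C plus the parameters of the backing sketch."""

    cutoff: int = 20
    spec: KmerSpec = field(default_factory=lambda: KmerSpec(k=20, canonical=True))
    n_tables: int = DEFAULT_N_TABLES
    table_size: int = DEFAULT_TABLE_SIZE

    def __post_init__(self) -> None:
        if self.cutoff < 1:
            raise ConfigurationError(f"cutoff must be >= 1, got {self.cutoff}")
        if self.cutoff >= COUNTER_CAP:
            raise ConfigurationError(
                f"cutoff {self.cutoff} must be below the counter cap {COUNTER_CAP}"
            )


@dataclass
class DiginormReport:
    """Per-run tallies; n_seen == n_kept + n_discarded + n_skipped_no_kmers."""

    n_seen: int = 0
    n_kept: int = 0
    n_discarded: int = 0
    n_skipped_no_kmers: int = 0


def normalize_by_median(
    reads,
    params: DiginormParams,
    sketch: CountMinSketch | None = None,
) -> tuple[list, DiginormReport]:
    """Single-pass median-abundance normalization.

    Returns ``(kept_reads, report)``.  Kept reads are the original record
    objects, untouched and in input order.  Reads yielding zero valid k-mers
    (shorter than k, or every window containing an ambiguous base) are
    dropped and tallied separately.  Pass ``sketch`` to resume from a saved
    counting table; its KmerSpec must match ``params.spec``.
    """
    if sketch is None:
        sketch = CountMinSketch(
            params.spec, HashFamily.from_request(params.table_size, params.n_tables)
        )
    elif sketch.spec != params.spec:
        raise ConfigurationError(
            f"backing sketch has {sketch.spec}, parameters demand {params.spec}"
        )
    report = DiginormReport()
    kept: list = []
    cutoff = params.cutoff
    for rec in reads:
        report.n_seen += 1
        seq = rec.sequence if hasattr(rec, "sequence") else rec
        _, codes = sequence_codes(seq, params.spec)
        if codes.size == 0:
            report.n_skipped_no_kmers += 1
            continue
        counts = sketch.counts_for_codes(codes)
        counts.sort()
        median = int(counts[counts.size // 2])
        if median < cutoff:
            kept.append(rec)
            sketch.add_codes(codes)
            report.n_kept += 1
        else:
            report.n_discarded += 1
    return kept, report


def estimate_retained_coverage(kept_reads, reference_length: int) -> float:
    """Total kept bases divided by the reference length (fold coverage)."""
    if reference_length <= 0:
        raise ConfigurationError(f"reference_length must be positive, got {reference_length}")
    total = 0
    for rec in kept_reads:
        seq = rec.sequence if hasattr(rec, "sequence") else rec
        total += len(seq)
    return total / reference_length
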