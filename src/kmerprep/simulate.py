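"""Synthetic genomes and error-bearing shotgun reads.

Every test and worked example in this package runs on simulated data, so the
generator is first-class code: a uniform i.i.d. random genome, and reads
drawn at uniform random start positions on either strand with independent
per-base substitution errors at a fixed rate.  All output is a pure function
of the parameters and seed — identical seeds give byte-identical files.

The model is deliberately minimal: substitutions only (no indels), constant
Q40 qualities, no GC or positional bias.  That is enough to exercise
canonicalization, abundance counting, trimming and normalization end to
end; it does not emulate instrument-specific artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .kmer_core import KmerSpec, sequence_codes
from .seqio import SequenceRecord

__all__ = [
    "SimulationParams",
    "simulate_genome",
    "simulate_reads",
    "disjoint_genome_pair",
]

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_Q40 = "I"  # Phred+33 encoding of quality 40


@dataclass(frozen=True)
class SimulationParams:
    """Shotgun-read simulation settings.

    coverage is fold-coverage of the genome; error_rate is the per-base
    substitution probability.  With ``circular=True`` reads may wrap around
    the genome end, giving uniform coverage at every position (useful when a
    test's reasoning assumes no under-covered genome edges).
    """

    genome_length: int
    read_length: int = 100
    coverage: float = 20.0
    error_rate: float = 0.0
    seed: int = 0
    circular: bool = False

    def __post_init__(self) -> None:
        if self.read_length > self.genome_length:
            raise ConfigurationError(
                f"read_length {self.read_length} exceeds genome_length {self.genome_length}"
            )
        if not 0.0 <= self.error_rate < 1.0:
            raise ConfigurationError(f"error_rate must be in [0, 1), got {self.error_rate}")
        if self.coverage <= 0:
            raise ConfigurationError(f"coverage must be positive, got {self.coverage}")

    @property
    def n_reads(self) -> int:
        return round(self.coverage * self.genome_length / self.read_length)


def simulate_genome(length: int, seed: int) -> str:
    """Uniform i.i.d. ACGT string of the given length, reproducible per seed."""
    if length < 1:
        raise ConfigurationError(f"genome length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    return _BASE_BYTES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def simulate_reads(genome: str, params: SimulationParams) -> list[SequenceRecord]:
    """Simulate ``params.n_reads`` reads from ``genome``.

    Each read starts at a uniform random position, is reverse-complemented
    with probability 0.5, and has each base substituted (to a uniformly
    chosen different base) with probability ``error_rate``.  Qualities are a
    constant Q40.  Read descriptions record the true origin as
    ``pos=<start> strand=<+/->``.
    """
    rng = np.random.default_rng(params.seed)
    L = params.read_length
    g = np.frombuffer(genome.upper().encode("ascii"), dtype=np.uint8)
    code = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        code[b] = i
    gc = code[g]
    if (gc < 0).any():
        raise ConfigurationError("genome must contain only ACGT")
    n = params.n_reads
    if params.circular:
        starts = rng.integers(0, len(genome), size=n)
        gc2 = np.concatenate([gc, gc[: L - 1]])
    else:
        starts = rng.integers(0, len(genome) - L + 1, size=n)
        gc2 = gc
    minus = rng.random(n) < 0.5
    mat = gc2[starts[:, None] + np.arange(L)[None, :]].astype(np.int8)
    mat[minus] = 3 - mat[minus][:, ::-1]
    if params.error_rate > 0:
        err = rng.random((n, L)) < params.error_rate
        shift = rng.integers(1, 4, size=int(err.sum()))
        mat[err] = (mat[err] + shift) % 4
    seq_bytes = _BASE_BYTES[mat]
    qual = _Q40 * L
    records = []
    for i in range(n):
        records.append(
            SequenceRecord(
                id=f"read{i}",
                sequence=seq_bytes[i].tobytes().decode("ascii"),
                quality=qual,
                description=f"pos={int(starts[i])} strand={'-' if minus[i] else '+'}",
            )
        )
    return records


def disjoint_genome_pair(length: int, k: int, seed: int) -> tuple[str, str]:
    """Two random genomes sharing no canonical k-mer.

    At the k values used here a shared k-mer between two random genomes is
    astronomically unlikely, but the pair is verified exactly and resampled
    if necessary, so callers can rely on disjointness unconditionally.
    """
    spec = KmerSpec(k=k, canonical=True)
    g1 = simulate_genome(length, seed)
    set1 = set(sequence_codes(g1, spec)[1].tolist())
    for attempt in range(100):
        g2 = simulate_genome(length, seed + 1_000_003 + attempt)
        set2 = set(sequence_codes(g2, spec)[1].tolist())
        if not (set1 & set2):
            return g1, g2
    raise RuntimeError("could not sample k-mer-disjoint genomes")  # pragma: no cover
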