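"""DNA alphabet handling, k-mer extraction, canonicalization, and hashing.

All sketch structures in this package share the conventions fixed here:

* k-mers are packed 2 bits per base (A=0, C=1, G=2, T=3, most significant
  base first) into a 64-bit word, which caps k at 32;
* in canonical mode a k-mer and its reverse complement are collapsed to the
  lexicographically smaller of the two, so both sequencing strands count as
  one entity (with this base ordering, lexicographic order on strings equals
  numeric order on packed codes);
* the packed code is scrambled through a fixed 64-bit finalizer
  (splitmix64-style constants) and reduced modulo each table's prime size.
  There is no per-run seeding: hash indices are identical across processes
  and platforms, so sketch files are portable and golden-value tests hold.

Windows containing a non-ACGT character (e.g. the ambiguity code N) are
skipped during k-mer extraction; the read itself is never edited or cleaned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError, InvalidAlphabetError, KmerLengthError

__all__ = [
    "KmerSpec",
    "HashFamily",
    "reverse_complement",
    "canonical",
    "iter_kmers",
    "hash_indices",
    "sequence_codes",
    "indices_for_codes",
    "decode_kmer",
    "mix64",
]

_BASES = "ACGT"
_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# base -> 2-bit code; -1 marks any character outside {A,C,G,T} (upper or lower)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_U64 = np.uint64


@dataclass(frozen=True)
class KmerSpec:
    """Word length and strand-collapsing policy shared by all structures.

    Parameters
    ----------
    k
        K-mer length in bases; must satisfy 1 <= k <= 32 so a k-mer fits a
        2-bit-packed 64-bit word.
    canonical
        When True (the default), a k-mer and its reverse complement are
        treated as the same entity.
    """

    k: int
    canonical: bool = True

    def __post_init__(self) -> None:
        if not isinstance(self.k, int) or isinstance(self.k, bool):
            raise ConfigurationError(f"k must be an integer, got {self.k!r}")
        if not 1 <= self.k <= 32:
            raise ConfigurationError(
                f"k must be between 1 and 32 (2-bit packing in a 64-bit word), got {self.k}"
            )


@dataclass(frozen=True)
class HashFamily:
    """One hash index per counter/bit table, derived from a single 64-bit mix.

    ``table_sizes`` holds one distinct prime per table; the index into table
    *i* is ``mix64(packed_canonical_kmer) mod table_sizes[i]``.  Distinct
    primes keep the per-table indices decorrelated even though they share one
    underlying 64-bit value.
    """

    table_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.table_sizes)
        object.__setattr__(self, "table_sizes", sizes)
        if len(sizes) == 0:
            raise ConfigurationError("need at least one table")
        if len(set(sizes)) != len(sizes):
            raise ConfigurationError(f"table sizes must be distinct, got {sizes}")
        if any(s < 3 for s in sizes):
            raise ConfigurationError(f"table sizes must be >= 3, got {sizes}")

    @classmethod
    def from_request(cls, approx_size: int, n_tables: int = 4) -> "HashFamily":
        """Pick the ``n_tables`` largest distinct primes <= ``approx_size``."""
        from sympy import isprime, prevprime  # deferred: sympy import is slow

        if n_tables < 1:
            raise ConfigurationError("n_tables must be >= 1")
        if approx_size < 3 + n_tables:
            raise ConfigurationError(
                f"approx table size {approx_size} too small for {n_tables} tables"
            )
        sizes: list[int] = []
        p = int(approx_size)
        if not isprime(p):
            p = prevprime(p)
        while len(sizes) < n_tables:
            sizes.append(p)
            if len(sizes) < n_tables:
                p = prevprime(p)
        return cls(tuple(sizes))

    @property
    def n_tables(self) -> int:
        return len(self.table_sizes)


def _check_alphabet(seq: str) -> str:
    up = seq.upper()
    if not _ALPHABET.issuperset(up):
        bad = sorted(set(up) - _ALPHABET)
        raise InvalidAlphabetError(
            f"sequence contains characters outside ACGTN: {bad}"
        )
    return up


def reverse_complement(seq: str) -> str:
    """Reverse complement of ``seq`` (upper-cased); N complements to N."""
    up = _check_alphabet(seq)
    return up.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str, spec: KmerSpec) -> str:
    """Collapse ``kmer`` with its reverse complement per ``spec``.

    Returns the lexicographically smaller of the k-mer and its reverse
    complement when ``spec.canonical``; palindromic k-mers map to themselves.
    """
    if len(kmer) != spec.k:
        raise KmerLengthError(
            f"k-mer {kmer!r} has length {len(kmer)}, spec demands k={spec.k}"
        )
    up = _check_alphabet(kmer)
    if not spec.canonical:
        return up
    rc = up.translate(_COMPLEMENT)[::-1]
    return up if up <= rc else rc


def mix64(x: np.ndarray) -> np.ndarray:
    """Fixed 64-bit finalizer applied to packed k-mer codes (vectorized).

    Uses the splitmix64 avalanche constants; deterministic across runs and
    platforms by construction.
    """
    z = x.astype(_U64, copy=True)
    z += _U64(0x9E3779B97F4A7C15)  # golden-ratio increment: no fixed point at 0
    z ^= z >> _U64(30)
    z *= _U64(0xBF58476D1CE4E5B9)
    z ^= z >> _U64(27)
    z *= _U64(0x94D049BB133111EB)
    z ^= z >> _U64(31)
    return z


def sequence_codes(seq: str, spec: KmerSpec) -> tuple[np.ndarray, np.ndarray]:
    """Packed canonical codes for every valid k-mer window of ``seq``.

    Returns ``(positions, codes)``: ``positions[i]`` is the 0-based start of
    the i-th valid window (windows containing non-ACGT characters are
    skipped), ``codes[i]`` its 2-bit-packed canonical code.  This is the
    vectorized workhorse behind k-mer iteration, counting and graph loading.
    """
    k = spec.k
    b = _CODE[np.frombuffer(seq.upper().encode("latin-1"), dtype=np.uint8)]
    if b.size < k:
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=_U64))
    valid = b >= 0
    ok = sliding_window_view(valid, k).all(axis=1)
    win = sliding_window_view(np.where(valid, b, 0).astype(_U64), k)
    # most-significant base first: weight 4^(k-1) ... 4^0
    fwd_w = _U64(4) ** np.arange(k, dtype=_U64)[::-1]
    codes = win @ fwd_w
    if spec.canonical:
        # reverse complement of window w: (3 - w[j]) at place value 4^j
        rc_w = _U64(4) ** np.arange(k, dtype=_U64)
        rc = (_U64(3) - win) @ rc_w
        codes = np.minimum(codes, rc)
    positions = np.nonzero(ok)[0].astype(np.int64)
    return positions, codes[ok]


def decode_kmer(code: int, k: int) -> str:
    """Unpack a 2-bit code back into its k-mer string."""
    out = []
    c = int(code)
    for _ in range(k):
        out.append(_BASES[c & 3])
        c >>= 2
    return "".join(reversed(out))


def iter_kmers(seq: str, spec: KmerSpec) -> Iterator[tuple[int, str]]:
    """Yield ``(position, canonical k-mer)`` for each valid window of ``seq``.

    Windows containing a non-ACGT character are silently skipped, preserving
    the original read untouched; sequences shorter than k yield nothing.
    """
    positions, codes = sequence_codes(seq, spec)
    for pos, code in zip(positions.tolist(), codes.tolist()):
        yield pos, decode_kmer(code, spec.k)


def n_skipped_windows(seq: str, spec: KmerSpec) -> int:
    """Number of length-k windows skipped because they contain non-ACGT bases."""
    total = max(0, len(seq) - spec.k + 1)
    return total - sequence_codes(seq, spec)[0].size


def indices_for_codes(codes: np.ndarray, family: HashFamily) -> np.ndarray:
    """Table indices for an array of packed codes; shape ``(n, n_tables)``."""
    mixed = mix64(np.asarray(codes, dtype=_U64))
    out = np.empty((mixed.size, family.n_tables), dtype=np.int64)
    for t, p in enumerate(family.table_sizes):
        out[:, t] = (mixed % _U64(p)).astype(np.int64)
    return out


def hash_indices(kmer: str, family: HashFamily, spec: KmerSpec) -> list[int]:
    """Deterministic per-table indices for one k-mer.

    Identical for a k-mer and its reverse complement when ``spec.canonical``.
    K-mers containing N (or any non-ACGT character) are rejected.
    """
    if len(kmer) != spec.k:
        raise KmerLengthError(
            f"k-mer {kmer!r} has length {len(kmer)}, spec demands k={spec.k}"
        )
    _, codes = sequence_codes(kmer, spec)
    if codes.size != 1:
        raise InvalidAlphabetError(f"k-mer {kmer!r} contains non-ACGT characters")
    return indices_for_codes(codes, family)[0].tolist()
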