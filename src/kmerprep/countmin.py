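"""Approximate k-mer abundance counting with a CountMin sketch.

A CountMin sketch holds N counter tables of distinct prime sizes.  Adding a
k-mer increments one cell per table (chosen by the shared hash family); the
reported abundance is the minimum over tables.  Collisions can only inflate
a cell, so the estimate never undercounts the true abundance — until the
8-bit saturating counters pin at 255, which is ample headroom for the
coverage cutoffs used in normalization and trimming.

Memory is fixed up front by the table sizes and independent of how many
distinct k-mers stream through, which is the point: abundance filtering of
sequencing data whose k-mer diversity exceeds RAM.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .errors import EmptySequenceError, SketchFileError
from .kmer_core import (
    HashFamily,
    KmerSpec,
    hash_indices,
    indices_for_codes,
    sequence_codes,
)

__all__ = ["CountMinSketch", "COUNTER_CAP"]

COUNTER_CAP = 255  # 8-bit saturating counters

_MAGIC = b"MKM1"
_VERSION = 1


class CountMinSketch:
    """N saturating 8-bit counter tables indexed by a shared hash family."""

    def __init__(self, spec: KmerSpec, family: HashFamily):
        self.spec = spec
        self.family = family
        self._tables = [np.zeros(p, dtype=np.uint8) for p in family.table_sizes]
        self.n_consumed = 0  # total k-mers added

    # -- single k-mer interface ------------------------------------------------

    def add(self, kmer: str) -> int:
        """Add one k-mer; returns its estimated count after the increment."""
        idx = hash_indices(kmer, self.family, self.spec)
        after = COUNTER_CAP
        for tab, i in zip(self._tables, idx):
            if tab[i] < COUNTER_CAP:
                tab[i] += 1
            after = min(after, int(tab[i]))
        self.n_consumed += 1
        return after

    def get(self, kmer: str) -> int:
        """Estimated abundance: minimum over tables; never mutates."""
        idx = hash_indices(kmer, self.family, self.spec)
        return min(int(tab[i]) for tab, i in zip(self._tables, idx))

    # -- vectorized interface over packed codes --------------------------------

    def add_codes(self, codes: np.ndarray) -> None:
        """Add an array of packed canonical codes (bulk counterpart of add)."""
        if codes.size == 0:
            return
        idx = indices_for_codes(codes, self.family)
        for t, tab in enumerate(self._tables):
            uniq, cnt = np.unique(idx[:, t], return_counts=True)
            vals = tab[uniq].astype(np.int64) + cnt
            tab[uniq] = np.minimum(vals, COUNTER_CAP).astype(np.uint8)
        self.n_consumed += int(codes.size)

    def counts_for_codes(self, codes: np.ndarray) -> np.ndarray:
        """Estimated counts for an array of packed codes (no mutation)."""
        if codes.size == 0:
            return np.empty(0, dtype=np.uint8)
        idx = indices_for_codes(codes, self.family)
        out = self._tables[0][idx[:, 0]]
        for t in range(1, len(self._tables)):
            out = np.minimum(out, self._tables[t][idx[:, t]])
        return out

    def counts_for_sequence(self, seq: str) -> tuple[np.ndarray, np.ndarray]:
        """``(positions, counts)`` for every valid k-mer window of ``seq``."""
        positions, codes = sequence_codes(seq, self.spec)
        return positions, self.counts_for_codes(codes)

    # -- sequence-level operations ---------------------------------------------

    def consume_sequence(self, seq: str) -> int:
        """Add every valid k-mer of ``seq`` in order; returns how many."""
        _, codes = sequence_codes(seq, self.spec)
        self.add_codes(codes)
        return int(codes.size)

    def median_count(self, seq: str) -> tuple[int, float, float]:
        """Median, mean and population stdev of the k-mer counts of ``seq``.

        Counts are queried, never added.  The median of n sorted counts is
        the element at index n//2 (upper median for even n) — the decision
        statistic of digital normalization.
        """
        _, counts = self.counts_for_sequence(seq)
        if counts.size == 0:
            raise EmptySequenceError(
                "sequence yields no valid k-mers (too short or all windows contain N)"
            )
        c = np.sort(counts)
        median = int(c[c.size // 2])
        return median, float(c.mean()), float(c.std())

    def abundance_distribution(self, reads) -> np.ndarray:
        """Histogram over abundance 0..255 of the *distinct* k-mers in ``reads``.

        Each distinct canonical k-mer contributes once, to the bin of its
        sketch count.  Distinctness is tracked with an exact set of packed
        codes, so this is meant for desk-scale diagnostics, not terabyte
        streams.
        """
        seen: set[int] = set()
        hist = np.zeros(COUNTER_CAP + 1, dtype=np.int64)
        for rec in reads:
            seq = rec.sequence if hasattr(rec, "sequence") else rec
            _, codes = sequence_codes(seq, self.spec)
            for code in codes.tolist():
                if code not in seen:
                    seen.add(code)
                    hist[self.counts_for_codes(np.array([code], dtype=np.uint64))[0]] += 1
        return hist

    # -- diagnostics -----------------------------------------------------------

    def fp_rate(self) -> float:
        """Probability a never-seen k-mer reports a nonzero count.

        Product over tables of the occupied-cell fraction: a false positive
        needs a collision in every table.
        """
        rate = 1.0
        for tab in self._tables:
            rate *= np.count_nonzero(tab) / tab.size
        return rate

    # -- serialization ---------------------------------------------------------

    def save(self, path) -> None:
        """Write the sketch to ``path`` (magic MKM1, header, raw tables)."""
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(
                struct.pack(
                    "<BBBB",
                    _VERSION,
                    self.spec.k,
                    1 if self.spec.canonical else 0,
                    len(self._tables),
                )
            )
            for p in self.family.table_sizes:
                fh.write(struct.pack("<Q", p))
            for tab in self._tables:
                fh.write(tab.tobytes())

    @classmethod
    def load(cls, path) -> "CountMinSketch":
        """Read a sketch written by :meth:`save`; validates every header field."""
        data = Path(path).read_bytes()
        if len(data) < 8:
            raise SketchFileError(f"{path}: truncated header (< 8 bytes)")
        if data[:4] != _MAGIC:
            raise SketchFileError(f"{path}: bad magic {data[:4]!r}, expected {_MAGIC!r}")
        version, k, canon, n_tables = struct.unpack("<BBBB", data[4:8])
        if version != _VERSION:
            raise SketchFileError(f"{path}: unsupported version {version}")
        if not 1 <= k <= 32:
            raise SketchFileError(f"{path}: invalid k {k} in header")
        off = 8
        if len(data) < off + 8 * n_tables:
            raise SketchFileError(f"{path}: truncated table-size block")
        sizes = struct.unpack_from(f"<{n_tables}Q", data, off)
        off += 8 * n_tables
        spec = KmerSpec(k=k, canonical=bool(canon))
        sketch = cls(spec, HashFamily(tuple(int(s) for s in sizes)))
        for t, p in enumerate(sizes):
            if len(data) < off + p:
                raise SketchFileError(f"{path}: truncated counter table {t}")
            sketch._tables[t] = np.frombuffer(
                data[off : off + p], dtype=np.uint8
            ).copy()
            off += p
        if off != len(data):
            raise SketchFileError(f"{path}: {len(data) - off} trailing bytes")
        return sketch
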