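"""Approximate k-mer presence set with implicit connectivity (node graph).

The node graph is a Bloom filter over canonical k-mers: N bit tables indexed
by the same hash family as the counting sketch.  Edges are implicit — two
k-mers are adjacent when they overlap by k-1 bases — so the graph supports
neighborhood queries, component traversal and read partitioning without
storing any edge list.  Membership has no false negatives; false positives
occur at a rate estimable from table occupancy and are kept negligible at
the occupancies these workflows run at.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .errors import InvalidAlphabetError, KmerLengthError, SeedNotFoundError, SketchFileError
from .kmer_core import (
    HashFamily,
    KmerSpec,
    canonical,
    hash_indices,
    indices_for_codes,
    iter_kmers,
    sequence_codes,
)

__all__ = ["NodeGraph"]

_MAGIC = b"MNG1"
_VERSION = 1

_EXT_BASES = "ACGT"


class _UnionFind:
    """Union-find over hashable keys with path compression."""

    def __init__(self):
        self._parent: dict = {}

    def find(self, x):
        parent = self._parent
        if x not in parent:
            parent[x] = x
            return x
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self._parent[rb] = ra


class NodeGraph:
    """Bloom-filter k-mer set with implicit (k-1)-overlap edges."""

    def __init__(self, spec: KmerSpec, family: HashFamily):
        self.spec = spec
        self.family = family
        # packed bit tables: table t has family.table_sizes[t] bits
        self._tables = [
            np.zeros((p + 7) // 8, dtype=np.uint8) for p in family.table_sizes
        ]
        self.n_added = 0  # add attempts that were new

    # -- membership ------------------------------------------------------------

    def _present(self, idx: list[int]) -> bool:
        for tab, i in zip(self._tables, idx):
            if not (tab[i >> 3] >> (i & 7)) & 1:
                return False
        return True

    def contains(self, kmer: str) -> bool:
        """True for every k-mer ever added (no false negatives); rare false
        positives for absent k-mers."""
        return self._present(hash_indices(kmer, self.family, self.spec))

    def add_node(self, kmer: str) -> bool:
        """Set the k-mer's bit in every table; True if it was new."""
        idx = hash_indices(kmer, self.family, self.spec)
        was_present = self._present(idx)
        for tab, i in zip(self._tables, idx):
            tab[i >> 3] |= np.uint8(1 << (i & 7))
        if not was_present:
            self.n_added += 1
        return not was_present

    def add_codes(self, codes: np.ndarray) -> None:
        """Bulk insertion of packed canonical codes."""
        if codes.size == 0:
            return
        idx = indices_for_codes(codes, self.family)
        for t, tab in enumerate(self._tables):
            i = idx[:, t]
            np.bitwise_or.at(tab, i >> 3, (1 << (i & 7)).astype(np.uint8))

    def contains_codes(self, codes: np.ndarray) -> np.ndarray:
        """Boolean membership for an array of packed codes."""
        if codes.size == 0:
            return np.empty(0, dtype=bool)
        idx = indices_for_codes(codes, self.family)
        out = np.ones(codes.size, dtype=bool)
        for t, tab in enumerate(self._tables):
            i = idx[:, t]
            out &= ((tab[i >> 3] >> (i & 7).astype(np.uint8)) & 1).astype(bool)
        return out

    def consume_sequence(self, seq: str) -> int:
        """Add every valid k-mer of ``seq``; returns how many windows."""
        _, codes = sequence_codes(seq, self.spec)
        self.add_codes(codes)
        return int(codes.size)

    # -- connectivity ----------------------------------------------------------

    def neighbors(self, kmer: str) -> set[str]:
        """Canonical forms of the present k-mers overlapping ``kmer`` by k-1.

        The 8 candidates are the right extensions ``kmer[1:] + b`` and left
        extensions ``b + kmer[:-1]`` for each base b; candidates reported
        present by the Bloom tables are returned (the query itself may appear
        as a self-loop, and rare false positives are possible).
        """
        if len(kmer) != self.spec.k:
            raise KmerLengthError(
                f"k-mer {kmer!r} has length {len(kmer)}, spec demands k={self.spec.k}"
            )
        up = kmer.upper()
        if set(up) - set(_EXT_BASES):
            raise InvalidAlphabetError(f"k-mer {kmer!r} contains non-ACGT characters")
        out: set[str] = set()
        suffix, prefix = up[1:], up[:-1]
        for b in _EXT_BASES:
            for cand in (suffix + b, b + prefix):
                c = canonical(cand, self.spec)
                if c not in out and self.contains(c):
                    out.add(c)
        return out

    def connected_component(
        self, seed_kmer: str, max_nodes: int | None = None
    ) -> tuple[set[str], bool]:
        """Breadth-first traversal from ``seed_kmer`` over implicit edges.

        Returns ``(nodes, truncated)``; the frontier is expanded in
        lexicographic order so traversals are reproducible.  Raises
        :class:`SeedNotFoundError` if the seed is absent.
        """
        seed = canonical(seed_kmer, self.spec)
        if not self.contains(seed):
            raise SeedNotFoundError(f"seed k-mer {seed_kmer!r} is not in the graph")
        visited: set[str] = {seed}
        frontier = [seed]
        while frontier:
            if max_nodes is not None and len(visited) >= max_nodes:
                # anything still on the frontier may have unexplored neighbors
                for node in frontier:
                    if self.neighbors(node) - visited:
                        return visited, True
                return visited, False
            frontier.sort()
            nxt: list[str] = []
            for node in frontier:
                for nb in sorted(self.neighbors(node)):
                    if nb not in visited:
                        if max_nodes is not None and len(visited) >= max_nodes:
                            return visited, True
                        visited.add(nb)
                        nxt.append(nb)
            frontier = nxt
        return visited, False

    # -- read partitioning -----------------------------------------------------

    def partition_reads(self, reads) -> dict[str, int]:
        """Group reads into connectivity components of their k-mers.

        The graph must already contain every read's k-mers.  K-mers observed
        in the reads are joined by union-find: consecutive k-mers within a
        read, plus any graph-adjacent pair (restricting neighbor candidates
        to observed k-mers, so Bloom false positives cannot bridge
        components).  Two reads share a partition id iff their k-mers fall in
        one component; ids are dense integers in first-seen read order, and
        reads with zero valid k-mers get the sentinel id 0.
        """
        uf = _UnionFind()
        first_kmer: dict[str, str | None] = {}
        observed: set[str] = set()
        order: list[str] = []
        for rec in reads:
            rid = rec.id if hasattr(rec, "id") else str(len(order))
            seq = rec.sequence if hasattr(rec, "sequence") else rec
            order.append(rid)
            kmers = [km for _, km in iter_kmers(seq, self.spec)]
            if not kmers:
                first_kmer[rid] = None
                continue
            first_kmer[rid] = kmers[0]
            uf.find(kmers[0])
            for a, b in zip(kmers, kmers[1:]):
                uf.union(a, b)
            observed.update(kmers)
        for km in observed:
            for nb in self.neighbors(km):
                if nb in observed:
                    uf.union(km, nb)
        labels: dict[str, int] = {}
        result: dict[str, int] = {}
        for rid in order:
            km = first_kmer[rid]
            if km is None:
                result[rid] = 0
                continue
            root = uf.find(km)
            if root not in labels:
                labels[root] = len(labels) + 1
            result[rid] = labels[root]
        return result

    # -- diagnostics -----------------------------------------------------------

    def fp_rate(self) -> float:
        """Estimated probability an absent k-mer is reported present."""
        rate = 1.0
        for tab, p in zip(self._tables, self.family.table_sizes):
            set_bits = int(np.unpackbits(tab).sum())
            rate *= set_bits / p
        return rate

    # -- serialization ---------------------------------------------------------

    def save(self, path) -> None:
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
    def load(cls, path) -> "NodeGraph":
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
        graph = cls(KmerSpec(k=k, canonical=bool(canon)), HashFamily(tuple(int(s) for s in sizes)))
        for t, p in enumerate(sizes):
            nbytes = (p + 7) // 8
            if len(data) < off + nbytes:
                raise SketchFileError(f"{path}: truncated bit table {t}")
            graph._tables[t] = np.frombuffer(data[off : off + nbytes], dtype=np.uint8).copy()
            off += nbytes
        if off != len(data):
            raise SketchFileError(f"{path}: {len(data) - off} trailing bytes")
        return graph
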