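# Methods

## Data model and conventions

All structures share one set of k-mer conventions, fixed in `kmer_core`:

* **Alphabet.** Sequences are read case-insensitively over {A, C, G, T, N}.
  Any length-k window containing a character outside {A, C, G, T} is skipped
  at extraction time; the read itself is never modified. This is a deliberate
  boundary: data cleaning that rewrites user sequences (e.g. deleting
  ambiguous bases) changes biology silently, so the only place ambiguity is
  handled is the one place it cannot alter the files — k-mer iteration. A
  helper reports how many windows were skipped per sequence.
* **Packing.** A k-mer is packed 2 bits per base (A=0, C=1, G=2, T=3, most
  significant base first) into a 64-bit word. This caps k at 32; requests
  outside 1 ≤ k ≤ 32 are rejected at `KmerSpec` construction. Typical
  working values of k are 20–30, comfortably inside the cap.
* **Canonicalization.** In canonical mode (the default everywhere) a k-mer
  and its reverse complement are one entity, represented by the
  lexicographically smaller string. Because the base order A<C<G<T matches
  the numeric order of the 2-bit codes, the canonical form is simply the
  smaller packed code, which keeps the vectorized path branch-free.
  Palindromic k-mers are their own canonical form.
* **Hashing.** The packed canonical code is passed through a fixed 64-bit
  avalanche finalizer (the splitmix64 constants, with the golden-ratio
  increment added first so code 0 is not a fixed point) and reduced modulo
  each table's size. There is no per-run seed: indices are identical across
  processes and platforms, saved sketch files are portable, and a
  golden-value test pins the mapping forever. Table sizes are the N largest
  distinct primes at or below a requested size (primes via sympy), keeping
  the per-table moduli coprime so one 64-bit value can serve all tables.

## CountMin counting sketch

N tables of 8-bit saturating counters (cap 255). `add` increments one cell
per table; `get` returns the minimum over tables. Properties relied on
elsewhere:

* *Overcount-only*: collisions can only inflate a cell, so
  `get(x) ≥ min(true(x), 255)` always; equality holds whenever x collided in
  at least one table with nothing (verified in tests against an exact
  dictionary counter). At the occupancies the workflows run at (tables of
  ~2·10⁶ cells against ≤ ~5·10⁵ k-mer insertions, < 1% occupied) agreement
  with exact counts exceeds 99% of distinct k-mers.
* *Saturation*: counters pin at 255. The downstream users of counts —
  normalization cutoffs (default 20) and trim cutoffs (default 2) — live
  far below the cap, so no "big count" extension is provided.
* The per-read decision statistic is the **upper median**: the element at
  index ⌊n/2⌋ of the sorted count list. For odd n this is the ordinary
  median; for even n the choice is arbitrary but must be fixed, and this
  one is documented and tested. `median_count` also reports mean and
  *population* standard deviation (ddof = 0).
* The abundance histogram (`abundance_distribution`) tracks distinctness
  with an exact in-memory set of packed codes. That is intentional: it is a
  desk-scale diagnostic, and an exact set keeps it oracle-comparable.

Serialization is a 4-byte magic (`MKM1`), a one-byte format version, k,
canonical flag, table count, per-table uint64 little-endian sizes, then raw
counter bytes. Every field is validated on load; truncation, wrong magic,
and trailing bytes are distinct, named errors rather than silent garbage.

## Node graph (Bloom-filter k-mer set)

The connectivity graph stores only node membership: N bit tables over the
same hash family (magic `MNG1` on disk). Edges are implicit — two k-mers
are adjacent iff they overlap by k−1 bases — so `neighbors` enumerates the
8 possible one-base extensions and returns those present. Membership has no
false negatives; false positives occur at roughly the product of table
occupancies, which the workflows keep far below 1%.

Traversal (`connected_component`) is breadth-first with the frontier
expanded in lexicographic order, making component enumeration reproducible.
A `max_nodes` bound truncates the walk and reports whether unexplored
neighbors remained.

**Partitioning.** Reads are grouped by union-find over the canonical k-mers
observed in the reads: consecutive k-mers within a read are joined, then
every observed k-mer is joined to its graph neighbors *that were themselves
observed in reads*. Restricting to observed k-mers means a Bloom false
positive can never bridge two components — a candidate neighbor either is a
real read k-mer (then the (k−1)-overlap is a real edge, independent of the
filter) or is ignored. Partition ids are dense integers assigned in
first-seen read order; reads yielding no valid k-mer get the sentinel id 0.
The grouping is invariant under read order up to relabeling.

## Digital normalization

One pass, in input order. For each read: look up (never add) the counts of
its k-mers in the backing sketch, take the upper median, and keep the read
iff `median < C` (strict). Only kept reads have their k-mers added. Two
consequences, both load-bearing and both tested:

* **Idempotence.** Re-running on the output with a fresh sketch keeps 100%
  of reads: each kept read replays exactly the sketch state it originally
  saw, so its median is unchanged and still below C.
* **Monotonicity.** The kept set at cutoff C is a subset of the kept set at
  any larger cutoff, for the same input order.

Reads yielding zero valid k-mers are dropped and tallied separately
(`n_skipped_no_kmers`) rather than crashing the stream or passing through
uncounted. Kept reads are emitted as the original record objects —
sequence, quality and header byte-identical. Pairing information is ignored;
reads are independent. Defaults: C = 20, k = 20, 4 tables of ~10⁶ cells.

## Abundance trimming and quality filtering

Trimming is two-pass: count the entire data set into a sketch, then scan
each read for the first position i whose k-mer count falls below
`min_count` (default 2). The read is truncated to its first i + k − 1 bases
(the bases wholly supported by abundant k-mers), with quality truncated
identically; if the survivor is shorter than `min_length` (default k) the
read is discarded. Reads are truncated, never split into fragments. The
rationale is the error signature: a single substitution poisons up to k
consecutive windows with abundance-1 k-mers, so the first low window marks
the first suspect base region.

`quality_filter` is deliberately minimal — mean Phred+33 score and minimum
length — so a complete pre-filter chain can run self-contained. It modifies
nothing; FASTA input combined with a quality threshold is a configuration
error because the check is impossible, not skippable.

## Synthetic data generator

The simulator is the package's specification of its study conditions:

* genome: uniform i.i.d. ACGT of requested length;
* reads: `round(coverage × genome_length / read_length)` reads at uniform
  random start positions, reverse-complemented with probability 0.5, then
  subjected to i.i.d. substitutions (to a uniformly chosen *different*
  base) at the requested per-base rate; qualities are a constant Q40;
* everything is a pure function of (parameters, seed): identical seeds give
  byte-identical FASTQ files;
* `circular=True` lets reads wrap the genome end. Linear sampling leaves
  genome edges under-covered, so edge k-mers routinely appear exactly once
  and would be indistinguishable from errors; tests whose logic assumes
  uniform coverage (trimming specificity, retained-coverage bands) use
  circular sampling. Linear remains the default because real genomes have
  ends.
* `disjoint_genome_pair` samples two genomes and verifies exactly that they
  share no canonical k-mer (resampling on collision, which at k = 20 is a
  ~10⁻⁶ event), so partition-recovery tests rely on disjointness as a
  certainty rather than a probability.

The model is intentionally austere: no indels, no quality decay, no GC
bias, no chimeras, no read pairing. Passing tests therefore demonstrate the
algorithms' correctness under their own assumptions — not robustness to
instrument-specific artifacts, which real data would add on top.

## Pipeline and retention bands

`pipeline.run_pipeline` chains quality-filter → count → filter-abund →
normalize-by-median, writing each intermediate and a JSON summary of
per-stage read counts. "Approximately the expected results" is made
concrete as per-stage retention bands shipped in
`data/retention_bands.json`: quality [0.95, 1.0], trimming survivors
[0.85, 0.96], normalization [0.6, 0.78]. The bands were measured once, from
ten seeded development runs at the pipeline's reference conditions (10 kb
genome, 100 bp reads, 50× circular coverage, 0.5% substitution rate — a
realistic short-read error magnitude — with default cutoffs), widened by a
safety margin, and frozen. Outputs are a pure function of input bytes and
parameters (gzip output uses a fixed mtime and omits the filename header),
so reruns are byte-identical.

## Numerical and interface choices

* Counter updates in bulk touch only the affected cells
  (`np.unique` + clamped add), so per-read sketch updates stay O(read
  length), not O(table size).
* Zero-length inputs are legal everywhere they can occur (empty files,
  empty streams, empty components are errors only where the operation is
  undefined, e.g. the median of zero k-mers).
* The CLI maps usage errors to exit 1 and data/configuration errors to exit
  2; the citation epilog goes to standard error on *every* invocation,
  including failures, and never to standard output. Help text is under
  golden-file test: changing any existing flag's name or meaning fails the
  suite, which is the executable form of the semantic-versioning promise.
* Problem sizes throughout the test and acceptance runs (10 kb genomes,
  100 bp reads, 10–50× coverage, sketches of 4 × ~2·10⁶ cells) were chosen
  as the smallest scales at which the probabilistic claims (collision
  rates < 1%, coverage concentration) hold comfortably; they complete in a
  few minutes on one CPU.

## Known limitations

* No paired-end awareness anywhere; mates are filtered independently.
* 8-bit counters only; abundances above 255 are indistinguishable.
* The node graph stores membership only — no compressed encoding, no edge
  annotations, no contig extraction.
* Partitioning holds all observed k-mer strings in memory (exact
  union-find); it is correct and order-invariant, but desk-scale.
* FASTQ is restricted to the 4-line dialect; multi-line FASTQ is rejected
  with a parse error naming the record.
* Assembly, adapter trimming, and streaming (single-pass) error trimming
  are out of scope.
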