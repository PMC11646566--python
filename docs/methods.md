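# Methods

This note records the models and procedures `rlfm` implements, the
conventions and numerical choices where the design was open, what the
synthetic fixtures do and do not emulate, and known limitations.

## Notation and data model

The index stores the BWT `B` of an ordered DNA string collection
`T = (P0, …, Pm−1)` concatenated with per-sequence sentinels. Sentinels are
ordered `$0 < $1 < … < $m−1 < A < C < G < T < N` during suffix sorting but
collapse to a single symbol code 0 in the stored BWT; sequence identity is
recovered only through the sentinel-rank table of the sampled suffix array.
All coordinates are 0-based, half-open. `n = |B|`, `m` is the sentinel count,
`r` the number of maximal runs; `C(a)` and `rank(a, k)` define
`π(a, k) = C(a) + rank(a, k)`, the LF-mapping when `a = B[k]`.

By default every input sequence is indexed together with its reverse
complement, interleaved as `P0, rc(P0), P1, rc(P1), …` — the double-strand
BWT. On such an index `occ(P) = occ(rc(P))` for every `P`, and the
bi-interval `(lo(P), lo(rc(P)), occ(P))` supports extension on either side:
forward extension by `a` is backward extension of the swapped interval by
`comp(a)`.

## Run-length store

`B` is kept as maximal runs grouped into blocks (split above 1024 runs,
target 512), each caching per-symbol marginal counts, so `rank` and dynamic
insertion cost a walk over blocks plus one block's runs — sublinear in `n`
and bounded by the grouping structure, never by the offset. Query-heavy
phases additionally build a static numpy run index (cumulative run ends plus
per-run symbol-count prefix sums) giving `O(log r)` rank via binary search;
it is built lazily after a burst of rank calls on an unmodified index and
invalidated by insertion, so interleaved insert/rank workloads fall back to
the block walk rather than thrashing rebuilds.

The serialized form (`RLB1`) tags each run with a nibble-coded symbol and a
1/2/4/8-byte length class, and ends with a CRC-32; round trips are
bit-identical. In-memory layout is deliberately unconstrained by the file
format.

## Construction

Batches are suffix-sorted by encoding the concatenation over an integer
alphabet of `m + 5` values (each sentinel distinct and below the bases) and
running a prefix-doubling sorter built on `numpy.lexsort`. Doubling is
`O(n log² n)` but vectorised; at the package's intended scale (megabases per
batch, default batch limit 8 Mb) it is not the bottleneck, and it needs no
compiled dependency.

Merging a batch BWT `B2` into the index `B1` follows the interleave
invariant: for each symbol of `B2`, its position in the merged BWT is its
position in `B2` plus the number of `B1`-suffixes smaller than the suffix it
precedes, accumulated by walking each incoming sequence backwards through
`π_B1`. The resulting positions are strictly increasing per construction, so
the insertions are applied as one linear interleave pass (the "ascending
cursor" reading of per-position insertion). The merged result is bit-exactly
the direct build of the concatenated collection, for any batching — the core
correctness property, tested on randomized collections.

Input folding: lowercase is uppercased and any non-ACGT letter becomes `N`
before indexing. Empty sequences are rejected.

## Exact queries

*Backward search* is the textbook interval recurrence. A query `N` makes the
interval vanish — `N` never matches anything, including `N` in the text; this
is the usual aligner convention. The raw bi-interval extension primitive,
however, implements the pure recurrence (summing `π` differences over all
symbols smaller than the complement, sentinel included), so text `N`s behave
uniformly there; the query-facing wrappers apply the vanishing rule.

*SMEM finding* iterates a three-pass routine per candidate start `i`:
backward extension over the first `min_len` symbols rejects hopeless starts
cheaply and returns the position after the failure; forward extension finds
the maximal end `e` (set to `|P|` when the whole remainder extends); a final
backward pass from `e` (through the symbol that stopped the forward pass)
returns the next start — the position after the last symbol at which the
interval still held `min_occ` occurrences, or `i + 1` when it never dropped.
Reported counts are bi-interval sizes, i.e. occurrences over both strands.

*Locating* uses suffix-array samples at BWT rows divisible by the rate `s`
(CLI default 64; tiny test indexes use 1–8) plus the sentinel-rank table.
The sampled-SA builder walks each sequence backward from its sentinel row,
recording the suffix's start offset within its own sequence — the semantic
contract, stated directly rather than via concatenated-string offsets.
`locate` maintains a pool of backward-extended intervals, always expanding
the largest (ties to the smaller `lo`), and resolves occurrences the moment
an interval brackets a sampled row or a sentinel; the multi-hit variant
dedupes by (sequence, offset) and stops at the requested count. Every row of
the original interval resolves eventually (at its sentinel at the latest), so
exhaustive locating returns exactly the occurrence set.

## Alignment

The query is represented by its prefix DAWG: the automaton whose states are
the end-position classes of the query's substrings (its suffix automaton,
built online; ≤ 2L−1 states for L > 1). Every distinct substring is spelled
by exactly one path from the start state, which is what makes a DP over the
DAWG equivalent to a DP over all substrings. The reference side is the trie
of substrings simulated on the index: a node is a bi-interval and its
children are the non-empty one-symbol extensions; nodes with equal
bi-intervals are the same state, which is precisely the DAWG merging rule
applied on the fly.

Orientation convention: both graphs are traversed left to right, reference
children enumerated by forward extension. (A mirror-image formulation
traverses right to left with backward extensions and start-position classes;
the two are equivalent up to reversal, and the left-to-right form keeps the
DAWG states equal to end-position classes, which is also what the tests
check against brute force.)

The affine-gap recurrence per cell `(u, v)`:

- `E` (query symbol consumed, reference fixed) propagates along query edges,
- `F` (reference consumed, query fixed) propagates along reference edges
  within one query node, via a worklist so multi-base deletions chain,
- `G = H(pred) + s(a, b)` for the edge-label pair, `H = max{G, E, F}`,

with match +1, mismatch −3, gap open 5, gap extension 2 by default (the
conventional BWA-SW-family values; all four are exposed as options, and every
oracle test scores both routes with the same scheme). `N` scores as a
mismatch against everything. Cells with `H ≤ 0` are dropped; per query node
only the top-`W` cells by `H` survive (ties prefer the larger interval, then
the smaller `lo`; default `W` = 25). With `W` unlimited the best local score
is exact — it equals full affine Smith–Waterman against every indexed
sequence and strand, which the suite verifies against an independent
quadratic oracle. Sentinels are never extension children, so alignments
cannot cross sequence boundaries. No per-base traceback is produced; hits
carry the score, the bi-interval (whose size is the copy count), and the
aligned query/reference lengths.

The semi-global haplotype query runs the same engine on the plain query
chain: the only seed cell is (query start, interval of the empty string), so
the whole query must be consumed, while the reference side remains free at
both ends. Hits are the final-node cells with score ≥ `min_score`. The
`H > 0` retention is kept in this mode too, so an alignment whose running
prefix score dips to 0 or below — e.g. a mismatch within the first few query
bases at default scoring — is lost; this mirrors the banding heuristic's
known blind spot and is a documented limitation, not an error source the
redundancy filter can repair. Local restarts (zero-floor) are deliberately
disabled in semi-global mode.

Alternative gap placements of one locus surface as distinct but nested
bi-intervals; the redundancy filter processes hits by descending score and
drops a hit whose forward *or* reverse interval is contained in (or equal
to) that of a kept hit. Containment is non-strict: identical intervals
collapse. The filter is idempotent and order-independent given the fixed
ranking. It does not remove all conceivable overcounting — only
interval-nested redundancy.

Per-hit edit distances (used by the sliding-window profile) are computed by
locating one occurrence of the hit interval, decoding that haplotype, and
running a unit-cost alignment (edlib) of the query against the aligned
reference segment. The window profile extracts `window`-mers (default 101)
every `step` bases (default 50), and reports, per edit-distance threshold,
the summed copy counts of surviving hits. The default `min_score` for a
window is `match·window − maxed·(match + max(mismatch, gap_open + gap_ext))`
— the worst-case score of an alignment with `maxed` edits — so the score
filter never excludes hits the edit-distance buckets are supposed to count.

## Synthetic fixtures

The generator emulates the redundancy structure that motivates run-length
BWT indexing: `copies` haplotypes of one random base genome with per-base
Bernoulli SNPs (`snp_rate`), short 1–3 bp indels (`indel_rate`, kept ≥ 4 bp
apart so truth records stay independent), an optional presence/absence
segment carried by a fixed fraction of copies, and optional single-crossover
recombinants of two other copies. Everything derives from one
`numpy.random.default_rng(seed)`, so generation is byte-deterministic, and
every planted difference is emitted in a truth table.

What it does not emulate: sequencing error profiles, repeat families and
segmental duplications, GC bias, structural variants beyond one insertion
segment, or realistic linkage structure. Passing tests therefore demonstrate
algorithmic correctness on redundant collections with known ground truth,
not calibrated performance on real pangenomes.

Test and acceptance problem sizes are chosen to exercise the algorithms well
inside their stated ceilings: merge equivalence on 50 collections of up to
~3 kb, SMEM oracle equivalence on 200 instances (references up to 400 bp,
queries up to 60 bp), alignment exactness on 100 instances (references up to
400 bp per sequence, queries up to 50 bp), strand symmetry on 10⁴ substrings
of a 10 kb five-haplotype index, and the DAWG bound on 500 queries up to
63 bp. These are the package's own desk-scale study conditions.

## Degenerate inputs and tie-breaks

- Empty index: `n = 0`, backward search returns `[0, 0)`, serialization
  round-trips.
- Empty pattern: interval `[0, n)`; SMEM finding of a pattern shorter than
  `min_len` returns nothing.
- Locating an empty interval, decoding a sequence rank ≥ `m`, rank offsets
  outside `[0, n]`, zero/negative rates or bands: rejected with errors.
- Beam ties (equal `H`): larger interval first, then smaller `lo` —
  deterministic output across runs.
- Banded scores are monotone in `W` and bounded by the unbanded score on all
  tested instances; the beam is still a heuristic and this is a tested
  property of the implementation, not a theorem.

## Known limitations

- Pure Python plus numpy: construction throughput is desk-scale (megabases,
  not gigabases); the batch sorter materialises `8n`-byte integer arrays.
- The semi-global `H > 0` retention drops alignments with very early
  mismatches (see above), so haplotype counts near window edges can
  undercount carriers of a variant in the first few bases of a window.
- The redundancy filter is heuristic; non-nested redundant hits (e.g. the
  same locus reached through intervals that merely overlap) are not
  collapsed.
- The index format carries no record of whether it was built double-strand;
  strand attribution in CLI output assumes the double-strand layout unless
  `--single-strand` is passed.
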