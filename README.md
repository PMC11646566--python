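# rlfm — run-length FM-index toolkit for DNA sequence collections

Modern sequence collections — pangenomes, assembly archives, read sets — are
highly redundant: thousands of near-identical copies of the same genomic
regions. `rlfm` indexes such collections with a **run-length-encoded
multi-string Burrows–Wheeler Transform (BWT)** that, by default, contains both
strands of every sequence, and answers queries directly on the compressed
index:

- **exact counting** via backward search,
- **supermaximal exact matches (SMEMs)** with occurrence counts,
- **locating** occurrences through a sampled suffix array,
- **inexact local alignment** under affine-gap scoring by aligning the query's
  prefix DAWG against the BWT-simulated reference trie (revised BWA-SW), and
- **local-haplotype diversity**: for a query segment, the set of distinct
  haplotypes it aligns to end-to-end, each with its copy count in the index.

It is a pure-Python implementation aimed at method development and
desk-scale experiments, not at terabase production indexing.

## The model in brief

For an ordered collection `T = (P0, …, Pm−1)` joined by per-sequence sentinels
(`$0 < $1 < … < bases`, all stored as one symbol `$`), the BWT is
`B[i] = T[S(i)−1]` where `S` is the suffix array. With the cumulative count
`C(a)` and `rank(a, k)`, the mapping `π(a, k) = C(a) + rank(a, k)` drives
everything: backward search maps the suffix-array interval of `P` to that of
`aP`; the LF-walk `k ← π(B[k], k)` decodes sequences and recovers positions.

Construction is **incremental**: each batch of sequences is suffix-sorted
directly (sentinels encoded as `m` distinct integers below the bases) and its
BWT is merged into the growing index by computing, for every incoming symbol,
its position in the merged BWT — so the final index is independent of the
batching.

Because the index holds both strands, the **bi-interval**
`(lo(P), lo(rc(P)), occ(P))` can be extended in either direction with a single
index, which yields the three-pass SMEM algorithm and forward extension for
alignment. The aligner represents the query as its prefix DAWG (suffix
automaton, ≤ 2L−1 states), the reference as the trie of substrings simulated
on the BWT, and fills the affine-gap recurrence
`H = max{G, E, F}` over pairs of graph nodes, keeping the top-`W` cells per
query node (`W` unlimited ⇒ the best local score is exact). The semi-global
variant of the same DP, applied to the plain query chain, enumerates the local
haplotypes a segment matches; nested bi-intervals (alternative gap placements
of the same locus) are filtered out.

## Worked example

Simulate a small pangenome (6 haplotype copies of a 500 bp genome, SNP rate
0.01), index it, and query a 140 bp segment taken from the first haplotype:

```sh
rlfm simulate -o pan.fa --truth truth.tsv --length 500 --copies 6 --snp-rate 0.01 --seed 11
rlfm build pan.fa -o pan.rlb
rlfm stat pan.rlb
```

```
n	6012
m	12
r	1042
...
avg_run_length	5.770
```

The index holds 12 sequences (6 copies × 2 strands), 6012 symbols in 1042
runs — an average run length of 5.8 reflecting the fixture's redundancy.

```sh
rlfm mem pan.rlb q.fa --min-len 31 --locate 3
```

```
read1	0	140	1	0:120:+
```

One SMEM covers the whole query (`qstart=0`, `qend=140`), occurring once in
the index (the other copies carry SNPs inside the segment), located on the
forward strand of haplotype 0 at offset 120 — exactly where the segment was
cut out.

```sh
rlfm hapdiv pan.rlb q.fa --window 101 --step 20 --max-ed 0,1
```

```
query	start	end	count_ed0	count_ed1
read1	0	101	3	6
read1	20	121	1	4
```

The first 101-mer window matches 3 haplotype copies exactly and all 6 within
edit distance 1; the next window overlaps more planted SNPs, splitting the
counts further. This per-window count profile is the local-haplotype
diversity estimate.

Other subcommands: `rlfm merge` (append one index to another), `rlfm sw`
(local affine-gap alignment with `--band`), `rlfm build --no-reverse-complement`
for single-strand indexes.

## Index file format

`RLB1` magic, one version byte, `n` and `m` as 8-byte little-endian integers,
then one record per run — a header byte whose low nibble is the symbol code
(`$ A C G T N` = 0–5) and whose high nibble selects a 1/2/4/8-byte
little-endian run length — and a trailing CRC-32 of everything before it.
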