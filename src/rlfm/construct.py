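"""Incremental construction of the multi-string (double-strand) BWT.

Strategy: suffix-sort each batch of sequences directly (sentinels ordered
$0 < $1 < ... < all bases, realised by encoding the concatenation over an
integer alphabet of m + 5 values), then merge the batch BWT into the growing
index.  The merge computes, for every symbol of the incoming BWT, its position
in the merged BWT by walking each incoming sequence backwards while tracking
ranks in the existing BWT; the insertions are then applied in ascending merged
position in a single interleave pass.  The final BWT is independent of how the
input was batched.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .rlbwt import SENTINEL, SIGMA, RunLengthBWT, encode, normalize, revcomp

__all__ = ["SequenceBatch", "build_batch_bwt", "append_bwt", "incremental_build"]

#: default batch limit in bases, sized for desk use
DEFAULT_BATCH_LIMIT = 8_000_000


class SequenceBatch:
    """An ordered batch of DNA strings, optionally strand-augmented.

    With ``double_strand`` the effective list interleaves every sequence with
    its reverse complement: P0, rc(P0), P1, rc(P1), ...
    """

    def __init__(self, sequences: list[str], double_strand: bool = False):
        if any(len(s) == 0 for s in sequences):
            raise ValueError("empty sequence in batch")
        self.sequences = [normalize(s) for s in sequences]
        self.double_strand = double_strand

    def effective_sequences(self) -> list[str]:
        if not self.double_strand:
            return list(self.sequences)
        out: list[str] = []
        for s in self.sequences:
            out.append(s)
            out.append(revcomp(s))
        return out

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences)


def _suffix_array_ints(t: np.ndarray) -> np.ndarray:
    """Suffix array of an integer sequence by prefix doubling (numpy lexsort)."""
    n = len(t)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    rank = np.asarray(t, dtype=np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        if k < n:
            key2[:-k] = rank[k:]
        order = np.lexsort((key2, rank))
        r1 = rank[order]
        r2 = key2[order]
        newrank_sorted = np.zeros(n, dtype=np.int64)
        if n > 1:
            diff = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
            newrank_sorted[1:] = np.cumsum(diff)
        rank = np.empty(n, dtype=np.int64)
        rank[order] = newrank_sorted
        if newrank_sorted[-1] == n - 1:
            return order
        k *= 2


def build_batch_bwt(batch: SequenceBatch) -> RunLengthBWT:
    """BWT of the batch's concatenation with per-sequence ordered sentinels.

    The concatenation is encoded over the integer alphabet
    {$0 < $1 < ... < $m-1 < A < C < G < T < N} so that a plain suffix sort
    yields the multi-string suffix order; B[i] = T[S(i) - 1] with wrap-around.
    """
    seqs = batch.effective_sequences()
    if not seqs:
        raise ValueError("cannot build the BWT of an empty batch")
    m = len(seqs)
    n = sum(len(s) for s in seqs) + m
    t = np.empty(n, dtype=np.int64)
    pos = 0
    for i, s in enumerate(seqs):
        codes = encode(s)
        t[pos : pos + len(codes)] = codes.astype(np.int64) + m - 1
        pos += len(codes)
        t[pos] = i  # sentinel $i
        pos += 1
    sa = _suffix_array_ints(t)
    prev = t[sa - 1]  # numpy wraps index -1 to t[n-1]
    bwt_codes = np.where(prev < m, 0, prev - m + 1).astype(np.uint8)
    return RunLengthBWT.from_symbols(bwt_codes)


def append_bwt(b1: RunLengthBWT, b2: RunLengthBWT) -> RunLengthBWT:
    """Merge two multi-string BWTs: result indexes b1's sequences then b2's.

    For every symbol of b2 we first record its LF successor within b2, then walk
    each of b2's sequences backwards accumulating the symbol's rank among b1's
    suffixes; the sum of the two coordinates is the symbol's position in the
    merged BWT.  Positions come out sorted, so the insertions are applied with
    a single ascending interleave.
    """
    if b2.n == 0:
        return RunLengthBWT.from_symbols(b1.to_array())
    if b1.n == 0:
        return RunLengthBWT.from_symbols(b2.to_array())

    arr2 = b2.to_array()
    n2 = arr2.size
    m1, m2 = b1.m, b2.m

    # LF-mapping of b2, vectorised per symbol
    lf2 = np.empty(n2, dtype=np.int64)
    c2 = 0
    for a in range(SIGMA):
        idx = np.flatnonzero(arr2 == a)
        lf2[idx] = c2 + np.arange(idx.size)
        c2 += idx.size

    # static rank view of b1
    run_sym, run_end, occ = b1._build_cache()
    counts1 = [b1.symbol_count(a) for a in range(SIGMA)]
    c1 = np.concatenate(([0], np.cumsum(counts1)))[:SIGMA]
    n1 = b1.n

    def rank1(a: int, k: int) -> int:
        if k == 0:
            return 0
        if k == n1:
            return counts1[a]
        j = int(np.searchsorted(run_end, k, side="right"))
        x = int(occ[j, a])
        if run_sym[j] == a:
            x += k - (int(run_end[j - 1]) if j else 0)
        return x

    targets = np.empty(n2, dtype=np.int64)
    for i in range(m2):
        k = i
        l = m1
        while True:
            a = int(arr2[k])
            kp = int(lf2[k])
            targets[k] = k + l
            if a == SENTINEL:
                break
            l = int(c1[a]) + rank1(a, l)
            k = kp

    merged = np.empty(n1 + n2, dtype=np.uint8)
    mask = np.zeros(n1 + n2, dtype=bool)
    mask[targets] = True
    merged[targets] = arr2
    merged[~mask] = b1.to_array()
    return RunLengthBWT.from_symbols(merged)


def incremental_build(
    reader: Iterable,
    batch_limit: int = DEFAULT_BATCH_LIMIT,
    double_strand: bool = True,
) -> RunLengthBWT:
    """Build the BWT of a sequence stream batch by batch.

    ``reader`` yields DNA strings or (name, sequence) pairs.  The result is
    identical for any ``batch_limit``; batches only bound the memory of the
    suffix-sorting step.
    """
    bwt = RunLengthBWT()
    pending: list[str] = []
    pending_len = 0
    for rec in reader:
        seq = rec[1] if isinstance(rec, tuple) else str(rec)
        if len(seq) == 0:
            raise ValueError(f"empty sequence at record {bwt.m // (2 if double_strand else 1) + len(pending)}")
        pending.append(seq)
        pending_len += len(seq)
        if pending_len >= batch_limit:
            bwt = append_bwt(bwt, build_batch_bwt(SequenceBatch(pending, double_strand)))
            pending, pending_len = [], 0
    if pending:
        bwt = append_bwt(bwt, build_batch_bwt(SequenceBatch(pending, double_strand)))
    return bwt
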