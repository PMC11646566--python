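"""Exact-match queries: backward search, bidirectional extension on the
double-strand BWT, supermaximal exact matches, and locating via a sampled
suffix array.

Conventions: all coordinates are 0-based half-open.  A suffix-array interval
[lo, hi) collects the suffixes prefixed by a pattern P, so hi - lo = occ(P).
On a double-strand index the bi-interval (k, k2, s) additionally tracks the
interval start of the reverse complement, which makes forward extension a
backward extension of the complement.  Query symbols 'N' never match anything,
including 'N' in the indexed text.
"""

from __future__ import annotations

import heapq
from typing import NamedTuple

from .rlbwt import COMPLEMENT, SENTINEL, SIGMA, RunLengthBWT, encode

__all__ = [
    "SAInterval",
    "SABiInterval",
    "SmemHit",
    "SampledSuffixArray",
    "backward_search",
    "backward_ext",
    "forward_ext",
    "root_bi_interval",
    "find_smems",
    "index_ssa",
    "locate_one",
    "locate_many",
]

_N = 5  # symbol code of the ambiguity base


class SAInterval(NamedTuple):
    lo: int
    hi: int

    @property
    def size(self) -> int:
        return self.hi - self.lo


class SABiInterval(NamedTuple):
    """(lo(P), lo(rc(P)), occ(P)); swapping k and k2 gives rc(P)'s bi-interval."""

    k: int
    k2: int
    s: int

    def swap(self) -> "SABiInterval":
        return SABiInterval(self.k2, self.k, self.s)


class SmemHit(NamedTuple):
    start: int          # query interval [start, end)
    end: int
    bi: SABiInterval

    @property
    def count(self) -> int:
        return self.bi.s


def root_bi_interval(bwt: RunLengthBWT) -> SABiInterval:
    """Bi-interval of the empty string: (0, 0, n)."""
    return SABiInterval(0, 0, bwt.n)


def backward_search(bwt: RunLengthBWT, pattern: str) -> SAInterval:
    """SA interval of ``pattern``; the empty pattern maps to [0, n)."""
    lo, hi = 0, bwt.n
    for a in encode(pattern)[::-1]:
        if a == _N:
            return SAInterval(0, 0)
        lo = bwt.pi(a, lo)
        hi = bwt.pi(a, hi)
        if lo >= hi:
            return SAInterval(lo, lo)
    return SAInterval(lo, hi)


def backward_ext(bwt: RunLengthBWT, bi: SABiInterval, a: int) -> SABiInterval:
    """Bi-interval of aP from the bi-interval of P.

    k2 advances by the occurrence count of every extension b < comp(a),
    i.e. lo(rc(aP)) = lo(rc(P)) + sum_{b < comp(a)} occ(comp(b) P).
    """
    k, k2, s = bi
    ca = COMPLEMENT[a]
    for b in range(ca):
        cb = COMPLEMENT[b]
        k2 += bwt.rank(cb, k + s) - bwt.rank(cb, k)
    lo = bwt.rank(a, k)
    s_new = bwt.rank(a, k + s) - lo
    return SABiInterval(bwt.C(a) + lo, k2, s_new)


def forward_ext(bwt: RunLengthBWT, bi: SABiInterval, a: int) -> SABiInterval:
    """Bi-interval of Pa, via backward extension of the complement."""
    r = backward_ext(bwt, bi.swap(), COMPLEMENT[a])
    return r.swap()


def _ext_query(bwt: RunLengthBWT, bi: SABiInterval, a: int, forward: bool) -> SABiInterval:
    """Extension by a *query* symbol: N vanishes by convention."""
    if a == _N:
        return SABiInterval(bi.k, bi.k2, 0)
    return forward_ext(bwt, bi, a) if forward else backward_ext(bwt, bi, a)


def find_smems(
    bwt: RunLengthBWT,
    pattern: str,
    min_len: int = 1,
    min_occ: int = 1,
) -> list[SmemHit]:
    """Supermaximal exact matches of length >= min_len occurring >= min_occ times.

    Three-pass scheme per candidate start i: backward over P[i, i+min_len) to
    discard starts that cannot seed a long-enough match, forward extension to
    the maximal end e, then a fresh backward pass from e to find the next start
    capable of producing a longer match ending beyond e.
    """
    if min_len < 1 or min_occ < 1:
        raise ValueError("min_len and min_occ must be >= 1")
    p = encode(pattern)
    L = len(p)
    hits: list[SmemHit] = []

    def find1(i: int) -> int:
        if i + min_len > L:
            return L
        bi = root_bi_interval(bwt)
        for j in range(i + min_len - 1, i - 1, -1):  # backward
            bi = _ext_query(bwt, bi, int(p[j]), forward=False)
            if bi.s < min_occ:
                return j + 1
        for j in range(i + min_len, L):  # forward
            nxt = _ext_query(bwt, bi, int(p[j]), forward=True)
            if nxt.s < min_occ:
                e = j
                break
            bi = nxt
        else:
            e = L
        hits.append(SmemHit(i, e, bi))
        if e >= L:
            return L
        bi = root_bi_interval(bwt)
        for j in range(e, i, -1):  # backward again, through the failed symbol
            bi = _ext_query(bwt, bi, int(p[j]), forward=False)
            if bi.s < min_occ:
                return j + 1
        return i + 1

    i = 0
    while i < L:
        i = find1(i)
    return hits


class SampledSuffixArray:
    """Suffix-array samples: U/V map sampled BWT rows to (sequence, offset);
    R maps each sentinel rank to the sequence whose first symbol follows it."""

    def __init__(self, rate: int, u: dict[int, int], v: dict[int, int], r: dict[int, int]):
        self.rate = rate
        self.u = u  # BWT row // rate -> sequence id
        self.v = v  # BWT row // rate -> suffix start offset in that sequence
        self.r = r  # sentinel rank -> sequence id


def index_ssa(bwt: RunLengthBWT, rate: int) -> SampledSuffixArray:
    """Walk every sequence backwards from its sentinel row, recording samples.

    A BWT row visited at backward step w corresponds to the suffix starting at
    offset len(seq) - w; rows divisible by ``rate`` get (U, V) entries and the
    row carrying the sequence's leading sentinel gets an R entry.
    """
    if rate < 1:
        raise ValueError("sample rate must be >= 1")
    u: dict[int, int] = {}
    v: dict[int, int] = {}
    r: dict[int, int] = {}
    for t in range(bwt.m):
        k = t
        pending: list[tuple[int, int]] = []  # (sample slot, step)
        step = 0
        while True:
            a = bwt.symbol_at(k)
            if a == SENTINEL:
                r[bwt.rank(SENTINEL, k)] = t
                break
            step += 1
            k = bwt.pi(a, k)
            if k % rate == 0:
                pending.append((k // rate, step))
        length = step
        for slot, w in pending:
            u[slot] = t
            v[slot] = length - w
    return SampledSuffixArray(rate, u, v, r)


def _resolve_interval(
    bwt: RunLengthBWT, ssa: SampledSuffixArray, lo: int, hi: int, o: int
) -> list[tuple[int, int]]:
    """Occurrences immediately recoverable from [lo, hi): sampled rows and
    sentinel rows.  ``o`` symbols were prepended relative to the query."""
    out = []
    s = ssa.rate
    for slot in range((lo + s - 1) // s, (hi + s - 1) // s):
        if slot in ssa.u:
            out.append((ssa.u[slot], ssa.v[slot] + o))
    for j in range(bwt.rank(SENTINEL, lo), bwt.rank(SENTINEL, hi)):
        out.append((ssa.r[j], o))
    return out


def locate_one(bwt: RunLengthBWT, ssa: SampledSuffixArray, interval: SAInterval) -> tuple[int, int]:
    """One (sequence, offset) where the interval's string occurs.

    Largest-interval-first search: repeatedly backward-extend the interval by
    every symbol until some sub-interval brackets a sampled row or a sentinel.
    """
    hits = locate_many(bwt, ssa, interval, max_hits=1)
    return hits[0]


def locate_many(
    bwt: RunLengthBWT, ssa: SampledSuffixArray, interval: SAInterval, max_hits: int
) -> list[tuple[int, int]]:
    """Up to ``max_hits`` distinct (sequence, offset) occurrences."""
    lo, hi = interval
    if hi <= lo:
        raise ValueError("cannot locate an empty interval")
    if max_hits < 1:
        raise ValueError("max_hits must be >= 1")
    want = min(hi - lo, max_hits)
    found: dict[tuple[int, int], None] = {}
    # max-heap keyed by interval size, ties by smaller lo; counter breaks ties
    cnt = 0
    heap = [(-(hi - lo), lo, cnt, lo, hi, 0)]
    while heap and len(found) < want:
        _, _, _, l, h, o = heapq.heappop(heap)
        for pos in _resolve_interval(bwt, ssa, l, h, o):
            found.setdefault(pos)
            if len(found) >= want:
                break
        if len(found) >= want:
            break
        for a in range(1, SIGMA):
            la = bwt.pi(a, l)
            ha = bwt.pi(a, h)
            if ha > la:
                cnt += 1
                heapq.heappush(heap, (-(ha - la), la, cnt, la, ha, o + 1))
    return list(found)
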