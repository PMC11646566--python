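"""Inexact search: DAWG-to-trie dynamic programming under affine-gap scoring.

The query string is represented by its prefix DAWG (the directed acyclic word
graph whose states are the end-position classes of the query's substrings,
i.e. its suffix automaton), so that every distinct query substring is spelled
by exactly one path from the start state.  The reference side is the trie of
substrings simulated on the double-strand BWT: a node is a suffix-array
bi-interval, and its children are the non-empty single-symbol extensions.
Both graphs are traversed left to right; reference children are enumerated by
forward extension, which on a double-strand index is a backward extension of
the complement interval.  Merging reference nodes with equal bi-intervals
deduplicates states exactly as the DAWG merging rule prescribes.

Per query node only the ``band`` highest-scoring reference cells are kept
(top-W beam); with an unlimited band the best local score is exact.  The
semi-global mode requires the query to align end to end and reports every
reference state reachable with a positive full-length score — the local
haplotype set — with multiplicity equal to the interval size.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import NamedTuple, Optional

import edlib

from .query import (
    SABiInterval,
    SAInterval,
    SampledSuffixArray,
    forward_ext,
    index_ssa,
    locate_one,
)
from .rlbwt import RunLengthBWT, encode, normalize

__all__ = [
    "PrefixDAWG",
    "ScoringScheme",
    "AlignmentHit",
    "HaplotypeHit",
    "build_prefix_dawg",
    "bwasw",
    "hap_diversity",
    "filter_redundant",
    "window_diversity",
]

_N = 5
_NEG = float("-inf")


class PrefixDAWG:
    """Prefix DAWG (suffix automaton) of a query string.

    States are the end-position classes of the query's substrings; for a query
    of length L > 1 there are at most 2L - 1 states.  ``order`` is a
    topological order of the transition DAG and ``pre[u]`` lists the incoming
    edges of ``u`` as (predecessor, symbol-code) pairs.  State 0 is the start.
    """

    def __init__(self, pattern: str):
        if len(pattern) == 0:
            raise ValueError("cannot build the DAWG of an empty string")
        self.seq = normalize(pattern)
        codes = encode(self.seq)
        # online suffix-automaton construction
        self.length = [0]
        self.link = [-1]
        self.trans: list[dict[int, int]] = [{}]
        last = 0
        for c in codes:
            c = int(c)
            cur = len(self.length)
            self.length.append(self.length[last] + 1)
            self.link.append(-1)
            self.trans.append({})
            p = last
            while p != -1 and c not in self.trans[p]:
                self.trans[p][c] = cur
                p = self.link[p]
            if p == -1:
                self.link[cur] = 0
            else:
                q = self.trans[p][c]
                if self.length[p] + 1 == self.length[q]:
                    self.link[cur] = q
                else:
                    clone = len(self.length)
                    self.length.append(self.length[p] + 1)
                    self.link.append(self.link[q])
                    self.trans.append(dict(self.trans[q]))
                    while p != -1 and self.trans[p].get(c) == q:
                        self.trans[p][c] = clone
                        p = self.link[p]
                    self.link[q] = clone
                    self.link[cur] = clone
            last = cur
        self._last = last
        self.order = sorted(range(len(self.length)), key=self.length.__getitem__)
        self.pre: list[list[tuple[int, int]]] = [[] for _ in self.length]
        for u, edges in enumerate(self.trans):
            for a, v in edges.items():
                self.pre[v].append((u, a))

    @property
    def node_count(self) -> int:
        return len(self.length)

    @property
    def start(self) -> int:
        return 0

    def end_position_classes(self) -> set[frozenset[int]]:
        """End-position sets of the non-root states (1-based end offsets)."""
        endpos: list[set[int]] = [set() for _ in self.length]
        u = 0
        for i, c in enumerate(encode(self.seq), start=1):
            u = self.trans[u][int(c)]
            endpos[u].add(i)
        for u in sorted(range(len(self.length)), key=self.length.__getitem__, reverse=True):
            if self.link[u] >= 0:
                endpos[self.link[u]] |= endpos[u]
        return {frozenset(s) for i, s in enumerate(endpos) if i != 0}


def build_prefix_dawg(pattern: str) -> PrefixDAWG:
    return PrefixDAWG(pattern)


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring: a gap of length g costs gap_open + g * gap_ext."""

    match: int = 1
    mismatch: int = 3
    gap_open: int = 5
    gap_ext: int = 2

    def __post_init__(self) -> None:
        if self.match <= 0 or min(self.mismatch, self.gap_open, self.gap_ext) < 0:
            raise ValueError("match must be positive; penalties non-negative")

    def score(self, a: int, b: int) -> int:
        if a == b and a != _N:
            return self.match
        return -self.mismatch


class AlignmentHit(NamedTuple):
    score: int
    bi: SABiInterval
    ref_len: int
    query_len: int

    @property
    def count(self) -> int:
        return self.bi.s


class HaplotypeHit(NamedTuple):
    bi: SABiInterval
    score: int
    ref_len: int
    edit_distance: Optional[int] = None

    @property
    def count(self) -> int:
        return self.bi.s


class _Chain:
    """Query graph of a linear string, for semi-global alignment."""

    def __init__(self, pattern: str):
        if len(pattern) == 0:
            raise ValueError("empty query")
        self.seq = normalize(pattern)
        codes = encode(self.seq)
        n = len(codes) + 1
        self.order = list(range(n))
        self.pre = [[]] + [[(j, int(codes[j]))] for j in range(n - 1)]
        self.start = 0
        self.final = n - 1


# cell layout: [H, E, F, ref_len, query_len]
_H, _E, _F, _RD, _QD = range(5)


def _dp(graph, bwt: RunLengthBWT, scoring: ScoringScheme, band: Optional[int]):
    """Run the DAWG-vs-trie DP; returns per-node cell tables keyed by bi-interval."""
    q, e = scoring.gap_open, scoring.gap_ext
    root = (0, 0, bwt.n)
    child_cache: dict[tuple, list] = {}

    def children(vkey: tuple) -> list:
        res = child_cache.get(vkey)
        if res is None:
            bi = SABiInterval(*vkey)
            res = []
            for b in range(1, 6):
                c = forward_ext(bwt, bi, b)
                if c.s > 0:
                    res.append((b, (c.k, c.k2, c.s)))
            child_cache[vkey] = res
        return res

    cells: dict[int, dict[tuple, list]] = {
        graph.start: {root: [0, _NEG, _NEG, 0, 0]}
    }
    for u in graph.order:
        if u == graph.start:
            continue
        cur: dict[tuple, list] = {}

        def upd(vkey, h=None, ee=None, rd=0, qd=0):
            cell = cur.get(vkey)
            if cell is None:
                cell = [_NEG, _NEG, _NEG, 0, 0]
                cur[vkey] = cell
            if ee is not None and ee > cell[_E]:
                cell[_E] = ee
            if h is not None and h > cell[_H]:
                cell[_H] = h
                cell[_RD] = rd
                cell[_QD] = qd
            return cell

        for up, a in graph.pre[u]:
            for vkey, pc in cells.get(up, {}).items():
                hp = pc[_H]
                # insertion: consume the query symbol, reference unchanged
                enew = max(hp - q, pc[_E]) - e
                if enew > 0:
                    upd(vkey, h=enew, ee=enew, rd=pc[_RD], qd=pc[_QD] + 1)
                # match/mismatch: advance both sides
                for b, ckey in children(vkey):
                    sc = hp + scoring.score(a, b)
                    if sc > 0:
                        upd(ckey, h=sc, rd=pc[_RD] + 1, qd=pc[_QD] + 1)
        # deletions: advance the reference within the same query node; a
        # worklist propagates multi-symbol deletion chains
        work = deque(cur.keys())
        while work:
            vkey = work.popleft()
            cell = cur[vkey]
            base = max(cell[_H] - q, cell[_F]) - e
            if base <= 0:
                continue
            for b, ckey in children(vkey):
                tgt = cur.get(ckey)
                if tgt is None:
                    tgt = [_NEG, _NEG, _NEG, 0, 0]
                    cur[ckey] = tgt
                if base > tgt[_F]:
                    tgt[_F] = base
                    if base > tgt[_H]:
                        tgt[_H] = base
                        tgt[_RD] = cell[_RD] + 1
                        tgt[_QD] = cell[_QD]
                    work.append(ckey)
        # retention: positive cells only, then the top-band beam
        cur = {k: c for k, c in cur.items() if c[_H] > 0}
        if band is not None and len(cur) > band:
            ranked = sorted(cur.items(), key=lambda kv: (-kv[1][_H], -kv[0][2], kv[0][0]))
            cur = dict(ranked[:band])
        cells[u] = cur
    return cells


def bwasw(
    dawg: PrefixDAWG,
    bwt: RunLengthBWT,
    scoring: ScoringScheme = ScoringScheme(),
    band: Optional[int] = 25,
    max_hits: int = 100,
) -> list[AlignmentHit]:
    """Local alignment of the query DAWG against the BWT-simulated trie.

    Returns the best-scoring hits (one per reference bi-interval), sorted by
    score.  With ``band=None`` the best score is exact: it equals the affine
    Smith-Waterman maximum over every indexed sequence and strand.
    """
    cells = _dp(dawg, bwt, scoring, band)
    best: dict[tuple, AlignmentHit] = {}
    for u, table in cells.items():
        if u == dawg.start:
            continue
        for vkey, cell in table.items():
            hit = AlignmentHit(cell[_H], SABiInterval(*vkey), cell[_RD], cell[_QD])
            old = best.get(vkey)
            if old is None or hit.score > old.score:
                best[vkey] = hit
    out = sorted(best.values(), key=lambda h: (-h.score, -h.bi.s, h.bi.k))
    return out[:max_hits]


def hap_diversity(
    pattern: str,
    bwt: RunLengthBWT,
    scoring: ScoringScheme = ScoringScheme(),
    band: Optional[int] = 25,
    min_score: int = 1,
    ssa: Optional[SampledSuffixArray] = None,
) -> list[HaplotypeHit]:
    """Semi-global haplotype query: the whole pattern must align end to end.

    Returns the redundancy-filtered set of reference bi-intervals with
    full-query score >= min_score; each hit's count is the number of haplotype
    copies carrying that local haplotype.  When ``ssa`` is given, each hit's
    unit-cost edit distance to one located occurrence is computed as well.
    """
    chain = _Chain(pattern)
    cells = _dp(chain, bwt, scoring, band)
    hits = [
        HaplotypeHit(SABiInterval(*vkey), cell[_H], cell[_RD])
        for vkey, cell in cells.get(chain.final, {}).items()
        if cell[_H] >= min_score
    ]
    hits = filter_redundant(hits)
    if ssa is not None:
        hits = [h._replace(edit_distance=_hit_edit_distance(chain.seq, h, bwt, ssa))
                for h in hits]
    return hits


_decode_cache: dict[tuple[int, int], str] = {}


def _hit_edit_distance(
    query: str, hit: HaplotypeHit, bwt: RunLengthBWT, ssa: SampledSuffixArray
) -> int:
    seq_id, off = locate_one(bwt, ssa, SAInterval(hit.bi.k, hit.bi.k + hit.bi.s))
    key = (id(bwt), seq_id)
    seq = _decode_cache.get(key)
    if seq is None:
        seq = bwt.decode_sequence(seq_id)
        if len(_decode_cache) > 4096:
            _decode_cache.clear()
        _decode_cache[key] = seq
    segment = seq[off : off + hit.ref_len]
    return edlib.align(query, segment, task="distance")["editDistance"]


def filter_redundant(hits: list[HaplotypeHit]) -> list[HaplotypeHit]:
    """Drop hits whose forward or reverse interval lies inside a better hit's.

    Hits are processed in descending score; a hit is removed when its forward
    interval [k, k+s) or its reverse interval [k2, k2+s) is contained in
    (or equal to) the corresponding interval of an already-kept hit.  This
    collapses alternative gap placements of the same locus, which surface as
    nested bi-intervals.
    """
    ranked = sorted(hits, key=lambda h: (-h.score, -h.bi.s, h.bi.k, h.bi.k2))
    kept: list[HaplotypeHit] = []
    for h in ranked:
        contained = any(
            (k.bi.k <= h.bi.k and h.bi.k + h.bi.s <= k.bi.k + k.bi.s)
            or (k.bi.k2 <= h.bi.k2 and h.bi.k2 + h.bi.s <= k.bi.k2 + k.bi.s)
            for k in kept
        )
        if not contained:
            kept.append(h)
    return kept


def window_diversity(
    query_seq: str,
    bwt: RunLengthBWT,
    window: int = 101,
    step: int = 50,
    scoring: ScoringScheme = ScoringScheme(),
    thresholds: tuple[int, ...] = (0, 1, 2),
    band: Optional[int] = 25,
    min_score: Optional[int] = None,
    ssa: Optional[SampledSuffixArray] = None,
) -> list[dict]:
    """Sliding-window haplotype-diversity profile.

    Extracts ``window``-mers every ``step`` bases from ``query_seq``, runs the
    semi-global haplotype query on each, and reports per window the summed
    haplotype count of hits within each edit-distance threshold.
    """
    query_seq = normalize(query_seq)
    if window > len(query_seq):
        raise ValueError("window longer than the query sequence")
    if step < 1:
        raise ValueError("step must be >= 1")
    if ssa is None:
        ssa = index_ssa(bwt, 8)
    maxed = max(thresholds)
    if min_score is None:
        worst = scoring.match + max(scoring.mismatch, scoring.gap_open + scoring.gap_ext)
        min_score = max(1, scoring.match * window - maxed * worst)
    rows = []
    for start in range(0, len(query_seq) - window + 1, step):
        sub = query_seq[start : start + window]
        hits = hap_diversity(sub, bwt, scoring, band, min_score, ssa=ssa)
        row = {"start": start, "end": start + window}
        for thr in thresholds:
            row[f"count_ed{thr}"] = sum(
                h.count for h in hits
                if h.edit_distance is not None and h.edit_distance <= thr
            )
        rows.append(row)
    return rows
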