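"""Alignment tests: query DAWG, local DAWG-to-trie DP against an affine
Smith-Waterman oracle, semi-global haplotype queries and redundancy filtering."""

import numpy as np
import pytest

from rlfm.align import (
    HaplotypeHit,
    ScoringScheme,
    build_prefix_dawg,
    bwasw,
    filter_redundant,
    hap_diversity,
    window_diversity,
)
from rlfm.construct import SequenceBatch, build_batch_bwt
from rlfm.query import SABiInterval, index_ssa

from oracles import endpos_classes, mutate, random_dna, revcomp, smith_waterman_affine


class TestPrefixDawg:
    def test_all_distinct_symbols(self):
        assert build_prefix_dawg("ACGT").node_count == 5

    def test_homopolymer(self):
        d = build_prefix_dawg("AAAA")
        assert d.node_count == 5
        assert d.end_position_classes() == {
            frozenset({1, 2, 3, 4}), frozenset({2, 3, 4}),
            frozenset({3, 4}), frozenset({4}),
        }

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_prefix_dawg("")

    def test_node_bound_and_endpos_classes(self, rng):
        for _ in range(150):
            p = random_dna(rng, int(rng.integers(2, 48)))
            d = build_prefix_dawg(p)
            assert d.node_count <= 2 * len(p) - 1
            assert d.node_count == len(endpos_classes(p)) + 1
            assert d.end_position_classes() == endpos_classes(p)

    def test_topological_order_respects_edges(self, rng):
        p = random_dna(rng, 30)
        d = build_prefix_dawg(p)
        pos = {u: i for i, u in enumerate(d.order)}
        for u, edges in enumerate(d.trans):
            for v in edges.values():
                assert pos[u] < pos[v]


def _best_oracle(seqs, q, sc: ScoringScheme) -> int:
    return max(
        smith_waterman_affine(q, strand, sc.match, sc.mismatch, sc.gap_open, sc.gap_ext)
        for s in seqs
        for strand in (s, revcomp(s))
    )


class TestBwasw:
    def test_perfect_substring_match(self, rng):
        s = random_dna(rng, 200)
        b = build_batch_bwt(SequenceBatch([s], double_strand=True))
        q = s[50:70]
        hits = bwasw(build_prefix_dawg(q), b, band=25)
        assert hits[0].score == 20
        assert hits[0].count >= 1

    def test_exactness_against_sw_oracle(self, rng):
        sc = ScoringScheme()
        for _ in range(25):
            seqs = [random_dna(rng, int(rng.integers(60, 250)))
                    for _ in range(int(rng.integers(1, 3)))]
            b = build_batch_bwt(SequenceBatch(seqs, double_strand=True))
            if rng.random() < 0.6:
                s = seqs[0]
                i = int(rng.integers(0, len(s) - 25))
                q = mutate(rng, s[i : i + int(rng.integers(15, 40))],
                           int(rng.integers(0, 5)))
            else:
                q = random_dna(rng, int(rng.integers(10, 40)))
            hits = bwasw(build_prefix_dawg(q), b, sc, band=None)
            got = hits[0].score if hits else 0
            assert got == _best_oracle(seqs, q, sc)

    def test_one_mismatch_scored_like_oracle(self, rng):
        sc = ScoringScheme()
        s = random_dna(rng, 300)
        q = list(s[100:140])
        q[20] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[20]]
        q = "".join(q)
        b = build_batch_bwt(SequenceBatch([s], double_strand=True))
        hits = bwasw(build_prefix_dawg(q), b, sc, band=None)
        assert hits[0].score == _best_oracle([s], q, sc)

    def test_banded_scores_monotone_and_bounded(self, rng):
        sc = ScoringScheme()
        for _ in range(8):
            s = random_dna(rng, 300)
            i = int(rng.integers(0, 250))
            q = mutate(rng, s[i : i + 40], 3)
            b = build_batch_bwt(SequenceBatch([s, mutate(rng, s, 10)],
                                              double_strand=True))
            dawg = build_prefix_dawg(q)
            exact = bwasw(dawg, b, sc, band=None)[0].score
            prev = 0
            for w in (1, 2, 4, 8, 16):
                hits = bwasw(dawg, b, sc, band=w)
                score = hits[0].score if hits else 0
                assert prev <= score <= exact
                prev = score


class TestHapDiversity:
    def test_identical_copies_collapse_to_one_hit(self, rng):
        base = random_dna(rng, 400)
        b = build_batch_bwt(SequenceBatch([base] * 3, double_strand=True))
        q = base[100:180]
        hits = hap_diversity(q, b, min_score=len(q) - 5)
        assert len(hits) == 1 and hits[0].count == 3

    def test_snp_copy_splits_counts(self, rng):
        sc = ScoringScheme()
        base = random_dna(rng, 400)
        alt = list(base)
        alt[140] = {"A": "C", "C": "G", "G": "T", "T": "A"}[alt[140]]
        alt = "".join(alt)
        b = build_batch_bwt(SequenceBatch([base, base, alt], double_strand=True))
        ssa = index_ssa(b, 8)
        q = base[100:180]
        hits = hap_diversity(q, b, sc, min_score=len(q) - sc.match - sc.mismatch,
                             ssa=ssa)
        by_count = sorted((h.count, h.score, h.edit_distance) for h in hits)
        assert by_count == [(1, len(q) - sc.match - sc.mismatch, 1),
                            (2, len(q), 0)]

    def test_ambiguous_gap_placements_collapse(self):
        # deleting one base of the query can be placed at several reference
        # positions around the same locus; the interval filter keeps one hit
        b = build_batch_bwt(SequenceBatch(["CAAGCAG"], double_strand=True))
        sc = ScoringScheme(match=2, mismatch=1, gap_open=1, gap_ext=1)
        hits = hap_diversity("AGCG", b, sc, band=None, min_score=4)
        assert len(hits) == 1

    def test_count_conservation_under_band(self, rng):
        base = random_dna(rng, 500)
        b = build_batch_bwt(SequenceBatch([base] * 7, double_strand=True))
        for start in (0, 150, 390):
            q = base[start : start + 101]
            hits = hap_diversity(q, b, band=25, min_score=101)
            assert sum(h.count for h in hits) == 7


class TestFilterRedundant:
    @staticmethod
    def _hit(k, k2, s, score):
        return HaplotypeHit(SABiInterval(k, k2, s), score, s)

    def test_identical_intervals_collapse(self):
        hits = [self._hit(3, 9, 2, 50), self._hit(3, 9, 2, 40)]
        kept = filter_redundant(hits)
        assert len(kept) == 1 and kept[0].score == 50

    def test_disjoint_intervals_kept(self):
        hits = [self._hit(0, 10, 2, 50), self._hit(5, 20, 2, 40)]
        assert len(filter_redundant(hits)) == 2

    def test_nested_forward_or_reverse_dropped(self):
        keep = self._hit(0, 100, 10, 50)
        nested_fwd = self._hit(2, 300, 3, 40)
        nested_rev = self._hit(200, 102, 3, 30)
        kept = filter_redundant([keep, nested_fwd, nested_rev])
        assert kept == [keep]

    def test_idempotent_and_order_independent(self, rng):
        hits = []
        for _ in range(40):
            k = int(rng.integers(0, 50))
            s = int(rng.integers(1, 10))
            hits.append(self._hit(k, int(rng.integers(0, 50)), s,
                                  int(rng.integers(1, 100))))
        kept = filter_redundant(hits)
        assert filter_redundant(kept) == kept
        perm = [hits[i] for i in rng.permutation(len(hits))]
        assert filter_redundant(perm) == kept
        # every dropped hit is contained in some kept hit of >= score
        for h in hits:
            if h in kept:
                continue
            assert any(
                k.score >= h.score
                and ((k.bi.k <= h.bi.k and h.bi.k + h.bi.s <= k.bi.k + k.bi.s)
                     or (k.bi.k2 <= h.bi.k2 and h.bi.k2 + h.bi.s <= k.bi.k2 + k.bi.s))
                for k in kept
            )


class TestWindowDiversity:
    def test_uniform_copies(self, rng):
        base = random_dna(rng, 350)
        b = build_batch_bwt(SequenceBatch([base] * 10, double_strand=True))
        rows = window_diversity(base, b, window=101, step=50, thresholds=(0,))
        assert rows and all(r["count_ed0"] == 10 for r in rows)

    def test_presence_absence_segment(self, rng):
        base = random_dna(rng, 500)
        seg = random_dna(rng, 200)
        carrier = base[:250] + seg + base[250:]
        copies = [carrier] * 4 + [base] * 6
        b = build_batch_bwt(SequenceBatch(copies, double_strand=True))
        rows = window_diversity(carrier, b, window=101, step=50, thresholds=(0,))
        by_start = {r["start"]: r["count_ed0"] for r in rows}
        # windows fully inside the inserted segment occur in carriers only
        assert by_start[300] == 4
        # windows fully outside occur in every copy
        assert by_start[0] == 10
        assert by_start[550] == 10

    def test_snp_splits_edit_distance_buckets(self, rng):
        base = random_dna(rng, 400)
        alt = list(base)
        alt[130] = {"A": "C", "C": "G", "G": "T", "T": "A"}[alt[130]]
        alt = "".join(alt)
        copies = [base] * 4 + [alt] * 2
        b = build_batch_bwt(SequenceBatch(copies, double_strand=True))
        rows = window_diversity(base, b, window=101, step=50, thresholds=(0, 1))
        by_start = {r["start"]: r for r in rows}
        assert by_start[50]["count_ed0"] == 4      # carriers differ by the SNP
        assert by_start[50]["count_ed1"] == 6
        assert by_start[250]["count_ed0"] == 6     # away from the SNP

    def test_window_longer_than_query_rejected(self, rng):
        b = build_batch_bwt(SequenceBatch(["ACGTACGT"], double_strand=True))
        with pytest.raises(ValueError):
            window_diversity("ACG", b, window=10)
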