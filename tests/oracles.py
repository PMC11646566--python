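"""Independent brute-force reference implementations used as test oracles.

Everything here works directly on plain Python strings (or dense numpy
arrays for the Smith-Waterman oracle) and never touches the FM-index code
paths it is used to check.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def effective_list(seqs: list[str], double_strand: bool) -> list[str]:
    if not double_strand:
        return list(seqs)
    out = []
    for s in seqs:
        out.append(s)
        out.append(revcomp(s))
    return out


def naive_multistring_bwt(seqs: list[str]) -> str:
    """BWT of the ordered collection by literally sorting all suffixes.

    Sentinels are ordered $0 < $1 < ... < all bases; the stored BWT collapses
    them to '$'.
    """
    m = len(seqs)
    order = {c: m + i for i, c in enumerate("ACGTN")}
    text: list[int] = []
    for i, s in enumerate(seqs):
        text.extend(order[c] for c in s)
        text.append(i)  # sentinel $i
    n = len(text)
    suffixes = sorted(range(n), key=lambda i: text[i:])
    out = []
    for i in suffixes:
        v = text[i - 1]  # i == 0 wraps to the final sentinel
        out.append("$" if v < m else "$ACGTN"[v - m + 1])
    return "".join(out)


def naive_occurrences(seqs: list[str], p: str) -> set[tuple[int, int]]:
    """All (sequence index, offset) where p occurs, overlapping included."""
    out = set()
    for t, s in enumerate(seqs):
        for i in range(len(s) - len(p) + 1):
            if s[i : i + len(p)] == p:
                out.add((t, i))
    return out


def occ_count(seqs: list[str], p: str) -> int:
    return len(naive_occurrences(seqs, p))


def maximal_exact_matches(t: str, p: str) -> list[tuple[int, int, int]]:
    """All maximal exact matches (t_start, p_start, length) by diagonal runs."""
    out = []
    for d in range(-len(p) + 1, len(t)):
        j = max(0, -d)
        i = j + d
        run = 0
        while i < len(t) and j < len(p):
            if t[i] == p[j]:
                run += 1
            else:
                if run:
                    out.append((i - run, j - run, run))
                run = 0
            i += 1
            j += 1
        if run:
            out.append((i - run, j - run, run))
    return out


def brute_smems(
    seqs: list[str], p: str, min_len: int, min_occ: int, double_strand: bool = True
) -> list[tuple[int, int, int]]:
    """SMEMs of p against the (optionally strand-augmented) collection.

    A query interval [i, e) is reported when p[i:e] occurs >= min_occ times,
    neither extension preserves that, and the interval is not contained in a
    longer such interval; the third field is the occurrence count.
    """
    eff = effective_list(seqs, double_strand)
    cands = set()
    for i in range(len(p)):
        e = i
        while e < len(p) and occ_count(eff, p[i : e + 1]) >= min_occ:
            e += 1
        if e > i:
            cands.add((i, e))
    out = []
    for i, e in sorted(cands):
        contained = any(
            a <= i and e <= b and (a, b) != (i, e) for a, b in cands
        )
        if not contained and e - i >= min_len:
            out.append((i, e, occ_count(eff, p[i:e])))
    return out


def smith_waterman_affine(
    p: str, t: str, match: int = 1, mismatch: int = 3, gap_open: int = 5, gap_ext: int = 2
) -> int:
    """Best local affine-gap alignment score of p against t (gap g costs
    gap_open + g*gap_ext); N matches nothing."""
    NEG = -(10**9)
    tp = np.frombuffer(t.encode(), dtype=np.uint8)
    H = np.zeros(len(t) + 1, dtype=np.int64)
    E = np.full(len(t) + 1, NEG, dtype=np.int64)
    best = 0
    for ch in p.encode():
        sub = np.where(tp == ch, match, -mismatch)
        if ch == ord("N"):
            sub[:] = -mismatch
        Hdiag = H[:-1]
        E = np.maximum(H - gap_open, E) - gap_ext
        Hnew = np.zeros_like(H)
        Hnew[1:] = np.maximum(np.maximum(Hdiag + sub, E[1:]), 0)
        F = NEG
        for j in range(1, len(t) + 1):  # horizontal gaps feed back into H
            F = max(Hnew[j - 1] - gap_open, F) - gap_ext
            if F > Hnew[j]:
                Hnew[j] = F
        H = np.maximum(Hnew, 0)
        b = int(H.max())
        if b > best:
            best = b
    return best


def endpos_classes(p: str) -> set[frozenset[int]]:
    """Distinct end-position sets (1-based end offsets) over all substrings."""
    classes = set()
    for i in range(len(p)):
        for j in range(i + 1, len(p) + 1):
            w = p[i:j]
            ends = frozenset(
                k + len(w)
                for k in range(len(p) - len(w) + 1)
                if p[k : k + len(w)] == w
            )
            classes.add(ends)
    return classes


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def random_collection(rng, max_seqs: int, min_len: int, max_len: int) -> list[str]:
    return [
        random_dna(rng, int(rng.integers(min_len, max_len + 1)))
        for _ in range(int(rng.integers(1, max_seqs + 1)))
    ]


def mutate(rng, s: str, n_edits: int) -> str:
    out = list(s)
    for _ in range(n_edits):
        if not out:
            break
        op = rng.random()
        pos = int(rng.integers(0, len(out)))
        if op < 0.6:
            out[pos] = "ACGT"[int(rng.integers(0, 4))]
        elif op < 0.8:
            out.insert(pos, "ACGT"[int(rng.integers(0, 4))])
        else:
            del out[pos]
    return "".join(out)
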