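"""Dynamic run-length-encoded multi-string BWT over the DNA alphabet.

The BWT string ``B`` is stored as maximal runs of equal symbols, grouped into
blocks that cache per-symbol marginal counts, so that ``rank`` and symbol
insertion cost a block traversal rather than a scan of the whole string.
Sequence collections are joined by per-sequence sentinels which are ordered
during suffix sorting but collapsed to one symbol code (0) in the stored BWT.

Symbol codes follow the sorting order ``$ < A < C < G < T < N``.
"""

from __future__ import annotations

import struct
import zlib
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "SENTINEL",
    "ALPHABET",
    "SIGMA",
    "COMPLEMENT",
    "encode",
    "decode",
    "revcomp",
    "normalize",
    "RunLengthBWT",
    "FormatError",
]

#: size of the sentinel-augmented alphabet {$, A, C, G, T, N}
SIGMA = 6
SENTINEL = 0
ALPHABET = "$ACGTN"

#: Watson-Crick complement per symbol code ($ and N are self-complementary)
COMPLEMENT = (0, 4, 3, 2, 1, 5)

_CODE = np.full(256, 5, dtype=np.uint8)  # unknown letters become N
for _i, _c in enumerate(ALPHABET):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i

# block sizing: split blocks above _BLOCK_MAX runs, merge tiny neighbours
_BLOCK_MAX = 1024
_BLOCK_TARGET = 512


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to symbol codes (anything non-ACGTN becomes N)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: Iterable[int]) -> str:
    return "".join(ALPHABET[c] for c in codes)


def normalize(seq: str) -> str:
    """Fold to uppercase and map every non-ACGT letter to N."""
    return decode(encode(seq))


def revcomp(seq: str) -> str:
    codes = encode(seq)
    return decode(COMPLEMENT[c] for c in codes[::-1])


class FormatError(ValueError):
    """Raised when a serialized index is malformed."""


class _Block:
    __slots__ = ("syms", "lens", "total", "counts")

    def __init__(self) -> None:
        self.syms: list[int] = []
        self.lens: list[int] = []
        self.total = 0
        self.counts = [0] * SIGMA

    @property
    def nruns(self) -> int:
        return len(self.syms)


class RunLengthBWT:
    """Multi-string BWT with run-length storage, rank and dynamic insertion.

    Parameters of interest per Table-style notation: ``n`` total symbols,
    ``m`` sentinel count, ``r`` number of maximal runs.
    """

    def __init__(self) -> None:
        self._blocks: list[_Block] = [_Block()]
        self._counts = [0] * SIGMA
        self._n = 0
        # lazily built static run index for query-heavy phases
        self._cache: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
        self._rank_calls_since_edit = 0

    # ------------------------------------------------------------------ basics
    @property
    def n(self) -> int:
        """Total number of symbols in B (equals |T|)."""
        return self._n

    @property
    def m(self) -> int:
        """Number of sentinels, i.e. number of indexed sequences."""
        return self._counts[SENTINEL]

    @property
    def r(self) -> int:
        """Number of maximal runs."""
        return sum(b.nruns for b in self._blocks)

    def symbol_count(self, a: int) -> int:
        return self._counts[a]

    def C(self, a: int) -> int:
        """Cumulative count of symbols strictly smaller than ``a``."""
        return sum(self._counts[:a])

    def runs(self) -> Iterator[tuple[int, int]]:
        """Yield maximal runs as (symbol, length) pairs."""
        for b in self._blocks:
            yield from zip(b.syms, b.lens)

    def to_array(self) -> np.ndarray:
        """Decode B into a dense uint8 symbol array."""
        out = np.empty(self._n, dtype=np.uint8)
        pos = 0
        for a, l in self.runs():
            out[pos : pos + l] = a
            pos += l
        return out

    def __str__(self) -> str:
        return decode(self.to_array())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RunLengthBWT):
            return NotImplemented
        return list(self.runs()) == list(other.runs())

    # ------------------------------------------------------------- construction
    @classmethod
    def from_symbols(cls, codes: np.ndarray | Iterable[int]) -> "RunLengthBWT":
        """Build from a dense symbol-code sequence (run-length encodes it)."""
        codes = np.asarray(list(codes) if not isinstance(codes, np.ndarray) else codes,
                           dtype=np.uint8)
        bwt = cls()
        if codes.size == 0:
            return bwt
        breaks = np.flatnonzero(np.diff(codes.astype(np.int16)) != 0) + 1
        starts = np.concatenate(([0], breaks))
        ends = np.concatenate((breaks, [codes.size]))
        bwt._load_runs(codes[starts].tolist(), (ends - starts).tolist())
        return bwt

    def _load_runs(self, syms: list[int], lens: list[int]) -> None:
        self._blocks = []
        for i in range(0, len(syms), _BLOCK_TARGET):
            b = _Block()
            b.syms = syms[i : i + _BLOCK_TARGET]
            b.lens = lens[i : i + _BLOCK_TARGET]
            b.total = sum(b.lens)
            for a, l in zip(b.syms, b.lens):
                b.counts[a] += l
            self._blocks.append(b)
        if not self._blocks:
            self._blocks = [_Block()]
        self._counts = [0] * SIGMA
        for b in self._blocks:
            for a in range(SIGMA):
                self._counts[a] += b.counts[a]
        self._n = sum(b.total for b in self._blocks)
        self._invalidate()

    # ------------------------------------------------------------------- rank
    def _invalidate(self) -> None:
        self._cache = None
        self._rank_calls_since_edit = 0

    def _build_cache(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        syms = []
        lens = []
        for a, l in self.runs():
            syms.append(a)
            lens.append(l)
        run_sym = np.asarray(syms, dtype=np.uint8)
        run_len = np.asarray(lens, dtype=np.int64)
        run_end = np.cumsum(run_len)
        occ = np.zeros((len(syms) + 1, SIGMA), dtype=np.int64)
        if len(syms):
            onehot = np.zeros((len(syms), SIGMA), dtype=np.int64)
            onehot[np.arange(len(syms)), run_sym] = run_len
            np.cumsum(onehot, axis=0, out=occ[1:])
        self._cache = (run_sym, run_end, occ)
        return self._cache

    def rank(self, a: int, k: int) -> int:
        """Number of occurrences of symbol ``a`` in ``B[0:k)``."""
        if not 0 <= k <= self._n:
            raise IndexError(f"rank offset {k} out of range [0, {self._n}]")
        if k == 0:
            return 0
        if k == self._n:
            return self._counts[a]
        cache = self._cache
        if cache is None:
            self._rank_calls_since_edit += 1
            if self._rank_calls_since_edit > 64:
                cache = self._build_cache()
            else:
                return self._rank_blocks(a, k)
        run_sym, run_end, occ = cache
        j = int(np.searchsorted(run_end, k, side="right"))
        x = int(occ[j, a])
        if run_sym[j] == a:
            start = int(run_end[j - 1]) if j else 0
            x += k - start
        return x

    def _rank_blocks(self, a: int, k: int) -> int:
        acc = 0
        for b in self._blocks:
            if k >= b.total:
                k -= b.total
                acc += b.counts[a]
                if k == 0:
                    return acc
                continue
            for s, l in zip(b.syms, b.lens):
                if k <= 0:
                    break
                if s == a:
                    acc += min(l, k)
                k -= l
            return acc
        return acc

    def pi(self, a: int, k: int) -> int:
        """The mapping C(a) + rank(a, k); for a = B[k] this is LF(k)."""
        return self.C(a) + self.rank(a, k)

    def symbol_at(self, k: int) -> int:
        """B[k]."""
        if not 0 <= k < self._n:
            raise IndexError(f"offset {k} out of range [0, {self._n})")
        cache = self._cache
        if cache is not None:
            run_sym, run_end, _ = cache
            j = int(np.searchsorted(run_end, k, side="right"))
            return int(run_sym[j])
        for b in self._blocks:
            if k >= b.total:
                k -= b.total
                continue
            for s, l in zip(b.syms, b.lens):
                if k < l:
                    return s
                k -= l
        raise AssertionError("unreachable")

    # ------------------------------------------------------------------ insert
    def insert_symbol(self, a: int, k: int) -> None:
        """Insert symbol ``a`` after ``k`` existing symbols, keeping runs maximal."""
        if not 0 <= k <= self._n:
            raise IndexError(f"insert offset {k} out of range [0, {self._n}]")
        if not 0 <= a < SIGMA:
            raise ValueError(f"bad symbol code {a}")
        bi = 0
        while bi < len(self._blocks) - 1 and k >= self._blocks[bi].total:
            k -= self._blocks[bi].total
            bi += 1
        blk = self._blocks[bi]
        # locate the run containing offset k within the block; k == len(run)
        # normalizes to k == 0 at the next run so boundary merges are uniform
        ri = 0
        while ri < blk.nruns and k >= blk.lens[ri]:
            k -= blk.lens[ri]
            ri += 1
        if ri < blk.nruns and blk.syms[ri] == a:
            blk.lens[ri] += 1
        elif ri < blk.nruns and 0 < k < blk.lens[ri]:
            # split the run
            s, l = blk.syms[ri], blk.lens[ri]
            blk.syms[ri : ri + 1] = [s, a, s]
            blk.lens[ri : ri + 1] = [k, 1, l - k]
        else:
            # boundary between runs (k == 0 at run ri, or end of block)
            if k == 0 and ri > 0 and blk.syms[ri - 1] == a:
                blk.lens[ri - 1] += 1
            elif k == 0 and ri == 0 and bi > 0 and self._blocks[bi - 1].syms and \
                    self._blocks[bi - 1].syms[-1] == a:
                prev = self._blocks[bi - 1]
                prev.lens[-1] += 1
                prev.total += 1
                prev.counts[a] += 1
                self._counts[a] += 1
                self._n += 1
                self._invalidate()
                return
            else:
                blk.syms.insert(ri, a)
                blk.lens.insert(ri, 1)
        blk.total += 1
        blk.counts[a] += 1
        self._counts[a] += 1
        self._n += 1
        if blk.nruns > _BLOCK_MAX:
            self._split_block(bi)
        self._invalidate()

    def _split_block(self, bi: int) -> None:
        blk = self._blocks[bi]
        half = blk.nruns // 2
        right = _Block()
        right.syms = blk.syms[half:]
        right.lens = blk.lens[half:]
        blk.syms = blk.syms[:half]
        blk.lens = blk.lens[:half]
        for b in (blk, right):
            b.total = sum(b.lens)
            b.counts = [0] * SIGMA
            for a, l in zip(b.syms, b.lens):
                b.counts[a] += l
        self._blocks.insert(bi + 1, right)

    # ------------------------------------------------------------------ decode
    def decode_sequence(self, t: int) -> str:
        """Recover the ``t``-th indexed sequence (sentinel rank order) by LF-walk."""
        if not 0 <= t < self.m:
            raise IndexError(f"sequence rank {t} out of range [0, {self.m})")
        out: list[int] = []
        k = t
        a = self.symbol_at(k)
        while a != SENTINEL:
            out.append(a)
            k = self.pi(a, k)
            a = self.symbol_at(k)
        return decode(reversed(out))

    def decode_all(self) -> list[str]:
        return [self.decode_sequence(t) for t in range(self.m)]

    # --------------------------------------------------------------- serialize
    _MAGIC = b"RLB1"
    _VERSION = 1

    def serialize(self, path) -> None:
        """Write the binary index: magic, version, n, m, tagged-varint runs, crc32.

        Each run is one header byte (low nibble = symbol code, high nibble =
        length class 0..3) followed by the run length in 1, 2, 4 or 8
        little-endian bytes.
        """
        payload = bytearray()
        payload += self._MAGIC
        payload.append(self._VERSION)
        payload += struct.pack("<QQ", self._n, self.m)
        for a, l in self.runs():
            if l < 1 << 8:
                cls, fmt = 0, "<B"
            elif l < 1 << 16:
                cls, fmt = 1, "<H"
            elif l < 1 << 32:
                cls, fmt = 2, "<I"
            else:
                cls, fmt = 3, "<Q"
            payload.append(a | (cls << 4))
            payload += struct.pack(fmt, l)
        crc = zlib.crc32(bytes(payload))
        with open(path, "wb") as fh:
            fh.write(bytes(payload))
            fh.write(struct.pack("<I", crc))

    @classmethod
    def deserialize(cls, path) -> "RunLengthBWT":
        with open(path, "rb") as fh:
            data = fh.read()
        if len(data) < 25:
            raise FormatError("index file truncated")
        payload, (crc,) = data[:-4], struct.unpack("<I", data[-4:])
        if zlib.crc32(payload) != crc:
            raise FormatError("index checksum mismatch")
        if payload[:4] != cls._MAGIC:
            raise FormatError("bad magic: not an RLB1 index")
        if payload[4] != cls._VERSION:
            raise FormatError(f"unsupported index version {payload[4]}")
        n, m = struct.unpack_from("<QQ", payload, 5)
        syms: list[int] = []
        lens: list[int] = []
        pos = 21
        sizes = (1, 2, 4, 8)
        fmts = ("<B", "<H", "<I", "<Q")
        while pos < len(payload):
            hdr = payload[pos]
            a, lcls = hdr & 0x0F, hdr >> 4
            if a >= SIGMA or lcls > 3:
                raise FormatError(f"corrupt run header at byte {pos}")
            pos += 1
            if pos + sizes[lcls] > len(payload):
                raise FormatError("index file truncated inside a run record")
            (l,) = struct.unpack_from(fmts[lcls], payload, pos)
            pos += sizes[lcls]
            if syms and syms[-1] == a:
                raise FormatError("adjacent runs share a symbol")
            syms.append(a)
            lens.append(l)
        bwt = cls()
        bwt._load_runs(syms, lens)
        if bwt.n != n or bwt.m != m:
            raise FormatError("run stream disagrees with the recorded n/m")
        return bwt
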