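"""Synthetic pangenome fixtures and sequence I/O.

The fixture generator emulates the redundancy structure of real pangenome
collections: many near-identical haplotype copies of one base genome carrying
planted SNPs, short indels, an optional presence/absence insertion segment and
optional recombinant copies.  Generation is fully deterministic given the
seed, and every planted difference is reported in a truth table so tests can
verify counts against known ground truth.
"""

from __future__ import annotations

import csv
import gzip
import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "PangenomeFixture",
    "generate_pangenome",
    "read_sequences",
    "write_fasta",
    "write_tsv",
]

_BASES = np.array(list("ACGT"))


@dataclass
class PangenomeFixture:
    """Parameters of a synthetic haplotype collection.

    Rates are per-base Bernoulli probabilities.  ``insertion_carrier_fraction``
    of the copies receive a presence/absence segment of ``insertion_length``
    bases at ``insertion_position`` (default: genome midpoint).  With
    ``recombination_rate`` > 0 each copy is, with that probability, replaced
    by a single-crossover recombinant of two other copies.
    """

    length: int = 1000
    copies: int = 10
    snp_rate: float = 0.0
    indel_rate: float = 0.0
    insertion_length: int = 0
    insertion_carrier_fraction: float = 0.0
    insertion_position: int | None = None
    recombination_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1 or self.copies < 1:
            raise ValueError("length and copies must be >= 1")
        for name in ("snp_rate", "indel_rate", "insertion_carrier_fraction",
                     "recombination_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0 and not (name == "insertion_carrier_fraction" and v == 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _mutate_base(ch: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != ch]
    return choices[rng.integers(0, 3)]


def generate_pangenome(fixture: PangenomeFixture) -> tuple[list[tuple[str, str]], list[dict]]:
    """Generate haplotype copies plus a truth table of every planted difference.

    Returns ``(records, truth)`` where records are (name, sequence) pairs named
    ``hap0..hapN-1`` and truth rows carry copy, variant type, position (on the
    base genome), ref and alt alleles.
    """
    rng = np.random.default_rng(fixture.seed)
    base = _random_dna(rng, fixture.length)
    ins_pos = (fixture.insertion_position
               if fixture.insertion_position is not None else fixture.length // 2)
    ins_seg = _random_dna(rng, fixture.insertion_length) if fixture.insertion_length else ""
    n_carriers = int(round(fixture.copies * fixture.insertion_carrier_fraction))

    # per-copy planted variant lists: (pos, type, ref, alt)
    variant_sets: list[list[tuple[int, str, str, str]]] = []
    for c in range(fixture.copies):
        variants: list[tuple[int, str, str, str]] = []
        if fixture.snp_rate > 0:
            for pos in np.flatnonzero(rng.random(fixture.length) < fixture.snp_rate):
                pos = int(pos)
                variants.append((pos, "snp", base[pos], _mutate_base(base[pos], rng)))
        if fixture.indel_rate > 0:
            for pos in np.flatnonzero(rng.random(fixture.length) < fixture.indel_rate):
                pos = int(pos)
                if any(abs(pos - p) < 4 for p, *_ in variants):
                    continue
                size = int(rng.integers(1, 4))
                if rng.random() < 0.5:
                    variants.append((pos, "del", base[pos : pos + size], ""))
                else:
                    variants.append((pos, "ins", "", _random_dna(rng, size)))
        if c < n_carriers and ins_seg:
            variants.append((ins_pos, "segment_insertion", "", ins_seg))
        variant_sets.append(sorted(variants))

    truth: list[dict] = []
    # optional recombinants: single crossover between two other copies
    recombinant_of: dict[int, tuple[int, int, int]] = {}
    if fixture.recombination_rate > 0 and fixture.copies >= 3:
        for c in range(fixture.copies):
            if rng.random() < fixture.recombination_rate:
                others = [x for x in range(fixture.copies) if x != c and x not in recombinant_of]
                if len(others) < 2:
                    continue
                pa, pb = rng.choice(others, size=2, replace=False)
                bp = int(rng.integers(1, fixture.length))
                recombinant_of[c] = (int(pa), int(pb), bp)

    records: list[tuple[str, str]] = []
    for c in range(fixture.copies):
        if c in recombinant_of:
            pa, pb, bp = recombinant_of[c]
            variants = sorted(
                [v for v in variant_sets[pa] if v[0] < bp]
                + [v for v in variant_sets[pb] if v[0] >= bp]
            )
            truth.append({"copy": f"hap{c}", "type": "recombination",
                          "pos": bp, "ref": f"hap{pa}", "alt": f"hap{pb}"})
        else:
            variants = variant_sets[c]
        seq = list(base)
        for pos, kind, ref, alt in reversed(variants):
            if kind == "snp":
                seq[pos] = alt
            elif kind == "del":
                del seq[pos : pos + len(ref)]
            else:  # ins / segment_insertion
                seq[pos:pos] = list(alt)
            truth.append({"copy": f"hap{c}", "type": kind, "pos": pos,
                          "ref": ref, "alt": alt})
        records.append((f"hap{c}", "".join(seq)))
    truth.sort(key=lambda r: (r["copy"], r["pos"]))
    return records, truth


# --------------------------------------------------------------------- I/O

def _open_text(path):
    """Open plain or gzip-compressed text, auto-detected by magic bytes."""
    fh = open(path, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=fh))
    return io.TextIOWrapper(fh)


def read_sequences(path):
    """Yield (name, sequence) from FASTA or FASTQ, plain or gzipped.

    The format is detected from the first record character; record order is
    preserved and defines sequence rank order downstream.
    """
    with _open_text(path) as fh:
        head = fh.read(1)
        fh.seek(0)
        if head == "":
            return
        if head == ">":
            fmt = "fasta"
        elif head == "@":
            fmt = "fastq"
        else:
            raise ValueError(f"{path}: not FASTA or FASTQ (starts with {head!r})")
        idx = -1
        try:
            for idx, rec in enumerate(SeqIO.parse(fh, fmt)):
                yield rec.id, str(rec.seq)
        except ValueError as exc:
            raise ValueError(f"{path}: malformed {fmt} record {idx + 1}: {exc}") from exc


def write_fasta(records, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_tsv(rows, path_or_fh) -> None:
    """Write dict rows as TSV with a header from the first row's keys."""
    rows = list(rows)
    own = isinstance(path_or_fh, (str, bytes)) or hasattr(path_or_fh, "__fspath__")
    fh = open(path_or_fh, "w", newline="") if own else path_or_fh
    try:
        if rows:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()), delimiter="\t")
            writer.writeheader()
            writer.writerows(rows)
    finally:
        if own:
            fh.close()
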