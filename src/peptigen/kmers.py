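"""K-mer counting, reference subtraction and unitig assembly.

These three operations are the computational core of cancer-specific
proteome construction: tumor reads are decomposed into k-mers, k-mers
seen in the normal (mTEC) reference are removed, and the surviving
k-mers are reassembled into contigs for in silico translation.

K-mers are stored in canonical form — the lexicographic minimum of a
k-mer and its reverse complement — so that counting and subtraction are
robust to the sequencing strand.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "KmerTable",
    "Contig",
    "revcomp",
    "canonical",
    "count_kmers",
    "subtract_kmers",
    "assemble_contigs",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (case preserved per base)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Canonical form: min(kmer, revcomp(kmer)) under lexicographic order."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class KmerTable:
    """Multiset of canonical k-mers with occurrence counts.

    Invariants: every key has length ``k`` over {A,C,G,T}; counts >= 1.
    """

    k: int
    counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.counts)

    def __contains__(self, kmer: str) -> bool:
        return canonical(kmer) in self.counts

    def get(self, kmer: str, default: int = 0) -> int:
        return self.counts.get(canonical(kmer), default)

    def total(self) -> int:
        return sum(self.counts.values())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for kmer in sorted(self.counts):
                fh.write(f"{kmer}\t{self.counts[kmer]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, k: int | None = None) -> "KmerTable":
        counts: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                kmer, n = line.rstrip("\n").split("\t")
                counts[kmer] = int(n)
        if k is None:
            if not counts:
                raise ValueError("cannot infer k from an empty table")
            k = len(next(iter(counts)))
        return cls(k=k, counts=counts)


@dataclass(frozen=True)
class Contig:
    """Assembled sequence; every length-k window is a member of the source table."""

    sequence: str
    n_kmers: int

    def __len__(self) -> int:
        return len(self.sequence)


def count_kmers(reads: Iterable[str], k: int) -> KmerTable:
    """Count canonical k-mers over all reads.

    Windows containing an ambiguous base (N) are skipped; every other
    window contributes 1 to its canonical k-mer's count. Reads shorter
    than ``k`` contribute nothing. An empty result is a valid table.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    # accept a ReadSet-like object as well as a plain iterable of strings
    reads = getattr(reads, "reads", reads)
    counts: Counter[str] = Counter()
    for read in reads:
        read = read.upper()
        n = len(read)
        if n < k:
            continue
        if "N" not in read:
            for i in range(n - k + 1):
                counts[canonical(read[i : i + k])] += 1
        else:
            # split at N runs; count windows within each clean segment
            for segment in read.split("N"):
                if len(segment) >= k:
                    for i in range(len(segment) - k + 1):
                        counts[canonical(segment[i : i + k])] += 1
    return KmerTable(k=k, counts=dict(counts))


def subtract_kmers(
    sample: KmerTable,
    reference: KmerTable,
    min_reference_count: int = 2,
) -> KmerTable:
    """Remove sample k-mers present >= ``min_reference_count`` times in the reference.

    Mirrors the construction of cancer-specific k-mer databases: tumor
    k-mers present at least twice in the mTEC database are discarded;
    everything else is retained with its sample count intact. A k-mer
    absent from the reference counts as 0 and is always retained.
    """
    if sample.k != reference.k:
        raise ValueError(
            f"incompatible tables: sample k={sample.k}, reference k={reference.k}"
        )
    ref = reference.counts
    kept = {
        kmer: n
        for kmer, n in sample.counts.items()
        if ref.get(kmer, 0) < min_reference_count
    }
    return KmerTable(k=sample.k, counts=kept)


def _oriented_successors(kmer: str, keys: set[str]) -> list[str]:
    suffix = kmer[1:]
    return [suffix + b for b in _BASES if canonical(suffix + b) in keys]


def _oriented_predecessors(kmer: str, keys: set[str]) -> list[str]:
    prefix = kmer[:-1]
    return [b + prefix for b in _BASES if canonical(b + prefix) in keys]


def _walk(start: str, keys: set[str], used: set[str]) -> list[str]:
    """Extend right from ``start`` while the extension is unique.

    Unique means: the current k-mer has exactly one successor and that
    successor has exactly one predecessor. Stops at branches, at already
    consumed k-mers, and at reverse-complement palindromes (ambiguous
    orientation).
    """
    path = [start]
    cur = start
    while True:
        succ = _oriented_successors(cur, keys)
        if len(succ) != 1:
            break
        nxt = succ[0]
        cn = canonical(nxt)
        if cn in used or nxt == revcomp(nxt):
            break
        if len(_oriented_predecessors(nxt, keys)) != 1:
            break
        used.add(cn)
        path.append(nxt)
        cur = nxt
    return path


def _path_sequence(path: list[str]) -> str:
    return path[0] + "".join(p[-1] for p in path[1:])


def assemble_contigs(table: KmerTable) -> list[Contig]:
    """Greedy unitig assembly on the (k-1)-overlap graph.

    Each canonical k-mer of the table ends up in exactly one contig;
    extension stops wherever it is not unique, so repeats break contigs
    at the branch instead of being resolved heuristically. Output is
    sorted by (length descending, sequence ascending) and each contig is
    emitted in its canonical orientation, making the result fully
    deterministic.
    """
    keys = set(table.counts)
    used: set[str] = set()
    contigs: list[Contig] = []
    for seed in sorted(keys):
        if seed in used:
            continue
        used.add(seed)
        right = _walk(seed, keys, used)
        left = _walk(revcomp(seed), keys, used)
        # left path extends the seed's reverse strand; flip it back
        left_seq = revcomp(_path_sequence(left))
        seq = left_seq[: -table.k] + _path_sequence(right)
        n_kmers = len(seq) - table.k + 1
        rc = revcomp(seq)
        contigs.append(Contig(sequence=min(seq, rc), n_kmers=n_kmers))
    contigs.sort(key=lambda c: (-len(c.sequence), c.sequence))
    return contigs


def contigs_to_fasta(contigs: Iterable[Contig], path: str | Path, prefix: str = "contig") -> None:
    with open(path, "w") as fh:
        for i, contig in enumerate(contigs, start=1):
            fh.write(f">{prefix}_{i} n_kmers={contig.n_kmers}\n{contig.sequence}\n")
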