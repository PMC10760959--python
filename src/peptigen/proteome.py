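"""Construction of the four MS search databases.

Canonical: annotated ORFs with TPM > 0, with sample single-base variants
applied, translated in their annotated frame.

ERE: endogenous-retroelement reads trimmed of ambiguous bases and
translated in all six frames (ERE reads are strand-ambiguous).

smRNA: 24-mer counting of small-RNA reads, contig assembly, 3-frame
translation, JJ-linked packing into ~10k-aa entries.

Cancer-specific: 33-mer counting of tumor reads, removal of k-mers seen
at least twice in the mTEC (normal thymic) k-mer database, contig
assembly of the remainder, 3-frame translation, JJ-linked packing.

The JJ linker joins polypeptides into large entries so that search
engines see few long sequences rather than many short ones; no 8–11-mer
candidate peptide can span a linker because J is not a residue the
candidate alphabet contains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .kmers import Contig, assemble_contigs, count_kmers, subtract_kmers
from .translate import six_frame, split_at_stops, three_frame, translate_orf

__all__ = [
    "ProteinDb",
    "build_canonical",
    "build_ere",
    "build_smrna",
    "build_cancer_specific",
    "KMER_LEN_CANCER",
    "KMER_LEN_SMRNA",
    "MIN_PEPTIDE_LEN",
    "ENTRY_SIZE_AA",
]

KMER_LEN_CANCER = 33
KMER_LEN_SMRNA = 24
MIN_PEPTIDE_LEN = 8
ENTRY_SIZE_AA = 10_000

LINKER = "JJ"


@dataclass
class ProteinDb:
    """Named collection of amino-acid entries with per-entry provenance."""

    name: str
    entries: list[tuple[str, str]] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def sequences(self) -> list[str]:
        return [seq for _, seq in self.entries]

    def add(self, entry_id: str, seq: str, source: str = "") -> None:
        if entry_id in self.provenance:
            raise ValueError(f"duplicate entry id: {entry_id}")
        self.entries.append((entry_id, seq))
        self.provenance[entry_id] = source

    def concat(self, other: "ProteinDb", name: str | None = None) -> "ProteinDb":
        merged = ProteinDb(name=name or f"{self.name}+{other.name}")
        for eid, seq in self.entries:
            merged.add(eid, seq, self.provenance.get(eid, ""))
        for eid, seq in other.entries:
            merged.add(eid, seq, other.provenance.get(eid, ""))
        return merged

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for eid, seq in self.entries:
                source = self.provenance.get(eid, "")
                header = f">{eid} {source}".rstrip()
                fh.write(f"{header}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")


def build_canonical(genome, tpm: dict[str, float], variants: Sequence[tuple[str, int, str, str]] = ()) -> ProteinDb:
    """Translate annotated ORFs with TPM > 0 after applying sample variants.

    ``variants`` are single-base substitutions (transcript id, 0-based
    position, ref, alt); a variant whose ref base does not match the
    transcript is rejected with a warning. Translation runs in the
    annotated frame (frame 0 of the ORF) and stops at the first stop
    codon.
    """
    by_tx: dict[str, list[tuple[int, str, str]]] = {}
    for tx_id, pos, ref, alt in variants:
        by_tx.setdefault(tx_id, []).append((pos, ref, alt))

    db = ProteinDb(name="canonical")
    for tx in genome.planted_transcripts:
        if tx.region != "exon":
            continue
        if tpm.get(tx.id, 0.0) <= 0.0:
            continue
        seq = tx.sequence
        for pos, ref, alt in by_tx.get(tx.id, []):
            if pos < 0 or pos >= len(seq):
                warnings.warn(f"variant position out of range for {tx.id}: {pos}")
                continue
            if seq[pos] != ref:
                warnings.warn(
                    f"variant rejected for {tx.id}: ref {ref!r} does not match "
                    f"{seq[pos]!r} at position {pos}"
                )
                continue
            seq = seq[:pos] + alt + seq[pos + 1 :]
        aa = translate_orf(seq)
        if aa:
            db.add(tx.id, aa, f"{tx.id}|frame0|orf")
    return db


def build_ere(ere_reads: Iterable[str], min_len: int = MIN_PEPTIDE_LEN, stop_mode: str = "split_all") -> ProteinDb:
    """Six-frame translate ERE reads into a theoretical ERE proteome.

    Reads are trimmed of leading/trailing N runs and split at internal
    Ns; each clean fragment is translated in all six frames, products
    are split at stop codons, and fragments of >= ``min_len`` aa are kept
    under unique ids.
    """
    db = ProteinDb(name="ere")
    n = 0
    for ridx, read in enumerate(ere_reads):
        read = read.upper().strip("N")
        for fidx, fragment in enumerate(read.split("N")):
            if len(fragment) < 3 * min_len:
                continue
            for strand, frame, aa in six_frame(fragment):
                for pidx, pep in enumerate(split_at_stops(aa, min_len, stop_mode)):
                    n += 1
                    db.add(
                        f"ere_{n:06d}",
                        pep,
                        f"read{ridx}.{fidx}|{strand}{frame}|p{pidx}",
                    )
    return db


def _pack_polypeptides(
    polypeptides: list[tuple[str, str]],
    db: ProteinDb,
    entry_prefix: str,
    entry_size: int = ENTRY_SIZE_AA,
) -> None:
    """Pack (source, peptide) pairs into JJ-linked entries of <= ``entry_size`` aa.

    Packing order is (length desc, sequence asc) for determinism; a
    polypeptide longer than ``entry_size`` still gets its own entry.
    """
    ordered = sorted(polypeptides, key=lambda p: (-len(p[1]), p[1]))
    block: list[str] = []
    sources: list[str] = []
    block_len = 0
    n_entry = 0

    def flush() -> None:
        nonlocal block, sources, block_len, n_entry
        if not block:
            return
        n_entry += 1
        db.add(
            f"{entry_prefix}_{n_entry:04d}",
            LINKER.join(block),
            ";".join(sources),
        )
        block, sources, block_len = [], [], 0

    for source, pep in ordered:
        added = len(pep) if not block else len(pep) + len(LINKER)
        if block and block_len + added > entry_size:
            flush()
            added = len(pep)
        block.append(pep)
        sources.append(source)
        block_len += added
    flush()


def _contigs_to_db(
    contigs: Sequence[Contig],
    name: str,
    min_len: int,
    entry_size: int,
    stop_mode: str,
) -> ProteinDb:
    db = ProteinDb(name=name)
    polypeptides: list[tuple[str, str]] = []
    for cidx, contig in enumerate(contigs, start=1):
        for frame, aa in three_frame(contig.sequence):
            for pidx, pep in enumerate(split_at_stops(aa, min_len, stop_mode)):
                polypeptides.append((f"contig{cidx}|+{frame}|p{pidx}", pep))
    _pack_polypeptides(polypeptides, db, entry_prefix=name, entry_size=entry_size)
    return db


def build_smrna(
    smrna_reads,
    k: int = KMER_LEN_SMRNA,
    min_len: int = MIN_PEPTIDE_LEN,
    entry_size: int = ENTRY_SIZE_AA,
    stop_mode: str = "split_all",
) -> ProteinDb:
    """Small-RNA proteome: 24-mer counting, contig assembly, 3-frame translation."""
    table = count_kmers(smrna_reads, k=k)
    contigs = assemble_contigs(table)
    return _contigs_to_db(contigs, "smrna", min_len, entry_size, stop_mode)


def build_cancer_specific(
    tumor_reads,
    mtec_reads,
    k: int = KMER_LEN_CANCER,
    min_reference_count: int = 2,
    min_len: int = MIN_PEPTIDE_LEN,
    entry_size: int = ENTRY_SIZE_AA,
    stop_mode: str = "split_all",
) -> ProteinDb:
    """Cancer-specific proteome by mTEC k-mer subtraction.

    Tumor 33-mers present at least ``min_reference_count`` times in the
    mTEC k-mer table are removed; the remainder is assembled into
    contigs, 3-frame translated, stop-split, and packed into JJ-linked
    entries.
    """
    tumor_table = count_kmers(tumor_reads, k=k)
    mtec_table = count_kmers(mtec_reads, k=k)
    specific = subtract_kmers(tumor_table, mtec_table, min_reference_count)
    contigs = assemble_contigs(specific)
    return _contigs_to_db(contigs, "cancer", min_len, entry_size, stop_mode)
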