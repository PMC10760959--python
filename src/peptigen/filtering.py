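"""Identification filtering: target-decoy FDR, length/binding-rank, L/I variants.

The false-discovery rate at a score threshold t is estimated as
(# decoy hits with score >= t) / (# target hits with score >= t); the
retained set is all targets at or above the smallest t whose estimate is
at or below the requested FDR. Ties at the threshold are kept on the
target side and counted on the decoy side — the conservative reading.

Candidates then pass the MHC I plausibility filters (length 8–11 aa,
best eluted-ligand rank over the sample's HLA alleles below 2%) and a
leucine/isoleucine disambiguation step: L and I are isobaric and
indistinguishable by standard MS, so a candidate whose L/I variant is a
known non-candidate peptide is discarded unless its own RNA expression
exceeds the variant's, or the variant maps to an unreliable region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from itertools import product
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .predictors import BindingPredictor, min_rank

__all__ = [
    "PeptideId",
    "fdr_threshold",
    "filter_candidates",
    "resolve_li_variants",
    "read_ids_tsv",
    "write_ids_tsv",
]

MIN_LEN = 8
MAX_LEN = 11
RANK_CUTOFF = 2.0
DEFAULT_FDR = 0.01

INADEQUATE_REGIONS = frozenset({"excluded-hypervariable", "excluded-discordant"})


@dataclass
class PeptideId:
    """One MS peptide identification."""

    sequence: str
    score: float
    is_decoy: bool
    sample_id: str
    best_rank: float | None = None
    best_allele: str | None = None
    is_true: bool | None = None  # ground-truth label, known for synthetic lists
    status: str = ""
    reason: str = ""


def fdr_threshold(
    ids: Sequence[PeptideId], fdr: float = DEFAULT_FDR
) -> tuple[float | None, list[PeptideId]]:
    """Sample-specific score threshold at the requested target-decoy FDR.

    Returns (threshold, retained targets). The threshold is the minimum
    score t such that decoys(>=t) / targets(>=t) <= fdr; if no score
    achieves that, nothing is retained and the threshold is None.
    """
    if not ids:
        raise ValueError("empty identification list")
    if not (0.0 < fdr < 1.0):
        raise ValueError(f"fdr must be in (0, 1), got {fdr}")
    targets = [p for p in ids if not p.is_decoy]
    if not targets:
        warnings.warn("no target identifications; nothing to retain")
        return None, []
    decoys = [p for p in ids if p.is_decoy]

    # scan candidate thresholds from high score to low, tracking counts
    scored = sorted(ids, key=lambda p: -p.score)
    best_t: float | None = None
    n_dec = 0
    n_tar = 0
    i = 0
    n = len(scored)
    while i < n:
        t = scored[i].score
        # absorb all records tied at score t
        while i < n and scored[i].score == t:
            if scored[i].is_decoy:
                n_dec += 1
            else:
                n_tar += 1
            i += 1
        if n_tar > 0 and n_dec / n_tar <= fdr:
            best_t = t  # keep lowering t while the estimate stays under fdr
    if best_t is None:
        return None, []
    retained = [replace(p, status="retained") for p in targets if p.score >= best_t]
    return best_t, retained


def filter_candidates(
    ids: Iterable[PeptideId],
    predictor: BindingPredictor,
    sample_alleles: Mapping[str, Sequence[str]],
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
    rank_cutoff: float = RANK_CUTOFF,
) -> list[PeptideId]:
    """Keep 8–11-mers whose best rank over the sample's alleles is < 2%."""
    kept: list[PeptideId] = []
    for p in ids:
        alleles = sample_alleles.get(p.sample_id)
        if not alleles:
            raise ValueError(f"sample {p.sample_id!r} has no HLA alleles configured")
        if not (min_len <= len(p.sequence) <= max_len):
            continue
        rank, allele = min_rank(predictor, p.sequence, alleles)
        if rank < rank_cutoff:
            kept.append(replace(p, best_rank=rank, best_allele=allele, status="candidate"))
    return kept


def li_variants(peptide: str) -> list[str]:
    """All sequences reachable by swapping L<->I at any subset of positions."""
    positions = [i for i, aa in enumerate(peptide) if aa in "LI"]
    out = []
    for combo in product(*(("L", "I") for _ in positions)):
        seq = list(peptide)
        for pos, aa in zip(positions, combo):
            seq[pos] = aa
        variant = "".join(seq)
        if variant != peptide:
            out.append(variant)
    return out


def resolve_li_variants(
    candidates: Sequence[PeptideId],
    non_candidates: Iterable[str],
    expression_lookup: Callable[[str, str], float],
    region_lookup: Callable[[str], str],
    inadequate_regions: frozenset[str] = INADEQUATE_REGIONS,
) -> list[PeptideId]:
    """Discard candidates shadowed by an L/I variant flagged non-candidate.

    ``expression_lookup(sequence, sample_id)`` returns the rphm of a
    peptide-coding sequence in the candidate's sample;
    ``region_lookup(sequence)`` its genomic-origin class. A candidate
    survives if it has no L/I variant in the non-candidate set, if its
    RNA expression exceeds every flagged variant's, or if the flagged
    variants all map to an unreliable region class (their flag carries
    no weight there).
    """
    flagged = set(non_candidates)
    kept: list[PeptideId] = []
    for p in candidates:
        hits = [v for v in li_variants(p.sequence) if v in flagged]
        if not hits:
            kept.append(replace(p, reason="no-li-variant"))
            continue
        relevant = [v for v in hits if region_lookup(v) not in inadequate_regions]
        if not relevant:
            kept.append(replace(p, reason="variant-in-inadequate-region"))
            continue
        own = expression_lookup(p.sequence, p.sample_id)
        if all(own > expression_lookup(v, p.sample_id) for v in relevant):
            kept.append(replace(p, reason="higher-expression-than-variant"))
    return kept


_TSV_COLUMNS = [
    "sequence",
    "score",
    "is_decoy",
    "sample_id",
    "best_allele",
    "best_rank",
    "status",
    "reason",
]


def write_ids_tsv(ids: Iterable[PeptideId], path: str | Path) -> None:
    rows = [
        {
            "sequence": p.sequence,
            "score": p.score,
            "is_decoy": p.is_decoy,
            "sample_id": p.sample_id,
            "best_allele": p.best_allele if p.best_allele is not None else "",
            "best_rank": p.best_rank if p.best_rank is not None else "",
            "status": p.status,
            "reason": p.reason,
        }
        for p in ids
    ]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_ids_tsv(path: str | Path) -> list[PeptideId]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            PeptideId(
                sequence=row.sequence,
                score=float(row.score),
                is_decoy=bool(row.is_decoy),
                sample_id=str(row.sample_id),
                best_allele=row.best_allele or None,
                best_rank=float(row.best_rank) if row.best_rank != "" else None,
                status=row.status,
                reason=row.reason,
            )
        )
    return out
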