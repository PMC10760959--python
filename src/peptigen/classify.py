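"""Antigen classification: genomic origin, then mTSA / aeTSA / TAA calls.

The decision workflow, applied in order to each MAP of interest (MOI):

1. Genomic origin. The MAP-coding sequence is exact-matched against the
   genome on both strands. Any exonic placement with at least one
   supporting read makes the origin exonic; otherwise the placement
   with the most supporting reads wins. Placements inside hypervariable
   regions (MHC/Ig/TCR-like loci) are excluded, as are sequences with
   no read-concordant placement; excluded origins reject the antigen.
2. Cohort prevalence. Antigens expressed above the cohort cutoff
   (default 2 rphm) in fewer than 5% of cohort samples are rejected as
   therapeutically uninteresting.
3. mTSA. A somatic variant in the MAP-coding sequence that matches no
   known germline polymorphism makes the antigen a mutated TSA.
4. aeTSA. If every normal tissue except the testis is non-expressing
   (no more than 10% of its samples above 8.55 rphm; mTECs count as a
   normal tissue), the antigen is an aberrantly expressed TSA. The
   testis is exempt because it is an immune-privileged site.
5. TAA. Otherwise the antigen is a tumor-associated antigen when the
   tumor-group mean expression is at least ``taa_fold`` (default 3x)
   times the highest mean among normal nonhematopoietic tissues
   (blood, marrow and mTECs are excluded from the comparator);
   otherwise it is rejected.

Every call carries an ordered rule trace with the evidence values that
produced it, so a call can be replayed and audited.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .expression import ExpressionProfile
from .kmers import revcomp

__all__ = [
    "Antigen",
    "AntigenCall",
    "GermlineVariantTable",
    "ClassifierParams",
    "assign_origin",
    "classify",
]

EXCLUDED_ORIGINS = frozenset({"excluded-hypervariable", "excluded-discordant"})

_TRACK_TO_ORIGIN = {
    "exon": "exonic",
    "intron": "intronic",
    "intergenic": "intergenic",
    "ERE": "ERE",
    "hypervariable": "excluded-hypervariable",
}


@dataclass(frozen=True)
class Antigen:
    """A candidate MAP with its coding sequence and observed variants."""

    id: str
    peptide: str
    coding_sequence: str
    origin: str = ""
    variants: tuple[tuple[int, str, str], ...] = ()  # (position, ref, alt)


@dataclass
class GermlineVariantTable:
    """Known germline polymorphisms as (coding-sequence position, ref, alt)."""

    variants: set[tuple[int, str, str]] = field(default_factory=set)

    def __contains__(self, variant: tuple[int, str, str]) -> bool:
        return variant in self.variants


@dataclass(frozen=True)
class ClassifierParams:
    normal_expr_threshold: float = 8.55  # rphm detection limit in normal tissues
    tissue_fraction: float = 0.10  # tissue expressing iff frac above threshold > this
    cohort_prevalence: float = 0.05
    cohort_expr_cutoff: float = 2.0  # rphm
    taa_fold: float = 3.0
    tumor_label: str = "tumor"
    testis_label: str = "testis"
    hematopoietic_labels: frozenset[str] = frozenset({"blood", "marrow", "mTEC"})


@dataclass
class AntigenCall:
    antigen_id: str
    label: str  # mTSA | aeTSA | TAA | rejected
    origin: str
    trace: list[tuple[str, str, dict]] = field(default_factory=list)


@dataclass(frozen=True)
class Placement:
    start: int
    end: int
    strand: str
    track_label: str
    origin: str
    reads: int


def _placement_origin(genome, start: int, end: int) -> tuple[str, str]:
    """(track label, origin class) of a genomic interval.

    Overlap with a hypervariable track dominates; otherwise the track
    with the largest overlap wins; intervals outside every track are
    intergenic. Tracks use 0-based half-open coordinates.
    """
    best_label, best_overlap = "", 0
    for track in genome.tracks:
        overlap = min(end, track.end) - max(start, track.start)
        if overlap <= 0:
            continue
        if track.label == "hypervariable":
            return "hypervariable", "excluded-hypervariable"
        if overlap > best_overlap:
            best_label, best_overlap = track.label, overlap
    if not best_label:
        return "intergenic", "intergenic"
    return best_label, _TRACK_TO_ORIGIN[best_label]


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _placement_read_support(genome, start: int, end: int, readsets, read_len: int) -> int:
    """Reads attributable to this placement: reads that lie within the
    placement's genomic context (placement extended by one read length
    on each side), on either strand, and overlap the placement itself.

    Exact substring containment in the local context distinguishes
    repeated placements of the same coding sequence by their flanks.
    """
    lo = max(0, start - read_len)
    hi = min(len(genome.sequence), end + read_len)
    context = genome.sequence[lo:hi]
    context_rc = revcomp(context)
    n = 0
    for rs in readsets:
        for read in rs.reads:
            if read in context or read in context_rc:
                n += 1
    return n


def assign_origin(
    coding_sequence: str,
    genome,
    readsets: Sequence | None = None,
) -> tuple[str, list[Placement]]:
    """Genomic origin of a MAP-coding sequence.

    Without read sets every placement counts one supporting read.
    Returns (origin, placements); origin is one of exonic, intronic,
    intergenic, ERE, excluded-hypervariable, excluded-discordant.
    """
    if len(coding_sequence) < 24:
        raise ValueError("coding sequence shorter than 24 nt")
    cs = coding_sequence.upper()
    seq = genome.sequence
    hits = [(i, "+") for i in _find_all(seq, cs)]
    hits += [(i, "-") for i in _find_all(seq, revcomp(cs))]
    if not hits:
        return "excluded-discordant", []

    read_len = 100
    if readsets:
        lengths = [len(r) for rs in readsets for r in rs.reads[:1]]
        if lengths:
            read_len = max(lengths)

    placements: list[Placement] = []
    for start, strand in sorted(set(hits)):
        end = start + len(cs)
        track_label, origin = _placement_origin(genome, start, end)
        if readsets is None:
            support = 1
        else:
            support = _placement_read_support(genome, start, end, readsets, read_len)
        placements.append(
            Placement(start=start, end=end, strand=strand,
                      track_label=track_label, origin=origin, reads=support)
        )

    valid = [p for p in placements if p.origin != "excluded-hypervariable"]
    if not valid:
        return "excluded-hypervariable", placements
    exonic = [p for p in valid if p.origin == "exonic" and p.reads >= 1]
    if exonic:
        return "exonic", placements
    supported = [p for p in valid if p.reads >= 1]
    if not supported:
        return "excluded-discordant", placements
    best = max(supported, key=lambda p: p.reads)
    return best.origin, placements


def classify(
    antigen: Antigen,
    profile: ExpressionProfile,
    germline: GermlineVariantTable,
    cohort_expression: Mapping[str, float],
    params: ClassifierParams = ClassifierParams(),
) -> AntigenCall:
    """Apply the ordered decision rules to one antigen.

    ``profile`` must cover the tumor group and the configured normal
    tissue panel; ``cohort_expression`` maps cohort sample ids to the
    rphm of the antigen's coding sequence.
    """
    call = AntigenCall(antigen_id=antigen.id, label="rejected", origin=antigen.origin)

    # rule 1: genomic origin must be usable
    if antigen.origin in EXCLUDED_ORIGINS:
        call.trace.append(("origin", "reject", {"origin": antigen.origin}))
        return call
    call.trace.append(("origin", "pass", {"origin": antigen.origin}))

    # rule 2: cohort prevalence
    if not cohort_expression:
        raise ValueError(f"no cohort expression for antigen {antigen.id!r}")
    n = len(cohort_expression)
    prevalence = sum(v > params.cohort_expr_cutoff for v in cohort_expression.values()) / n
    if prevalence < params.cohort_prevalence:
        call.trace.append(
            ("cohort-prevalence", "reject",
             {"prevalence": prevalence, "required": params.cohort_prevalence})
        )
        return call
    call.trace.append(("cohort-prevalence", "pass", {"prevalence": prevalence}))

    # rule 3: somatic (non-germline) variant -> mTSA
    somatic = [v for v in antigen.variants if v not in germline]
    if somatic:
        call.label = "mTSA"
        call.trace.append(("somatic-variant", "mTSA", {"variants": somatic}))
        return call
    call.trace.append(("somatic-variant", "none", {}))

    tissues = profile.group_summary
    normal = {
        t: s
        for t, s in tissues.items()
        if t != params.tumor_label and t != params.testis_label
    }
    missing = [params.tumor_label] if params.tumor_label not in tissues else []
    if missing:
        raise ValueError(f"profile missing tissue group(s): {missing}")

    # rule 4: silent in every normal tissue except testis -> aeTSA
    expressing_normals = sorted(t for t, s in normal.items() if s.expressing)
    if not expressing_normals:
        call.label = "aeTSA"
        call.trace.append(("normal-silence", "aeTSA", {"expressing_normals": []}))
        return call
    call.trace.append(
        ("normal-silence", "fail", {"expressing_normals": expressing_normals})
    )

    # rule 5: tumor overexpression vs normal nonhematopoietic tissues -> TAA
    tumor_mean = tissues[params.tumor_label].mean_rphm
    comparator = {
        t: s.mean_rphm
        for t, s in normal.items()
        if t not in params.hematopoietic_labels
    }
    max_normal = max(comparator.values(), default=0.0)
    if tumor_mean > 0 and tumor_mean >= params.taa_fold * max_normal:
        call.label = "TAA"
        call.trace.append(
            ("tumor-overexpression", "TAA",
             {"tumor_mean": tumor_mean, "max_normal_mean": max_normal,
              "fold": params.taa_fold})
        )
        return call
    call.trace.append(
        ("tumor-overexpression", "reject",
         {"tumor_mean": tumor_mean, "max_normal_mean": max_normal,
          "fold": params.taa_fold})
    )
    return call


def calls_to_tsv(calls: Sequence[AntigenCall], antigens: Mapping[str, Antigen], path: str | Path) -> None:
    rows = [
        {
            "antigen_id": c.antigen_id,
            "peptide": antigens[c.antigen_id].peptide if c.antigen_id in antigens else "",
            "label": c.label,
            "origin": c.origin,
            "trace": json.dumps(c.trace),
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
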