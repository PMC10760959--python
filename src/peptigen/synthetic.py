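"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators emulate the data the real analysis consumes:

* a genome with annotated exonic ORFs, introns, endogenous
  retroelement (ERE) insertions, a hypervariable region and intergenic
  space, plus planted transcripts, some of which are tumor-only;
* per-sample read sets (error-free exact substrings of expressed
  transcripts by default; an optional substitution-error rate is a
  config knob) in which tumor-only transcripts never contribute reads
  to normal tissues, so k-mer subtraction ground truth is exact;
* MS identification lists containing true peptides drawn from a search
  database, score-matched false targets, and reversed decoys whose
  scores follow the null distribution;
* a patient cohort with HLA genotypes drawn from an allele pool,
  per-antigen expression, and exponential survival whose hazard may
  depend on the number of presented antigens through a planted hazard
  ratio (hazard_ratio = 1 is the null).

All generators are deterministic for a given (seed, config) pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .predictors import DictBindingPredictor

__all__ = [
    "Track",
    "Transcript",
    "SyntheticGenome",
    "ReadSet",
    "CohortSample",
    "SyntheticCohort",
    "GenomeConfig",
    "SampleSpec",
    "ReadSimConfig",
    "IdSimConfig",
    "CohortConfig",
    "simulate_genome",
    "simulate_readsets",
    "simulate_identifications",
    "simulate_cohort",
    "default_panel",
]

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)

REGION_LABELS = ("exon", "intron", "intergenic", "ERE", "hypervariable")


@dataclass(frozen=True)
class Track:
    """0-based half-open annotated region."""

    label: str
    start: int
    end: int
    strand: str = "+"
    frame: int | None = None  # annotated ORF frame, exons only
    name: str = ""


@dataclass(frozen=True)
class Transcript:
    id: str
    sequence: str
    region: str
    tumor_only: bool


@dataclass
class SyntheticGenome:
    sequence: str
    tracks: list[Track]
    planted_transcripts: list[Transcript]

    def transcript(self, tx_id: str) -> Transcript:
        for tx in self.planted_transcripts:
            if tx.id == tx_id:
                return tx
        raise KeyError(tx_id)


@dataclass
class ReadSet:
    sample_id: str
    tissue_label: str
    reads: list[str]

    @property
    def total_reads(self) -> int:
        return len(self.reads)


@dataclass
class CohortSample:
    sample_id: str
    hla_alleles: list[str]
    expression: dict[str, float]  # antigen id -> rphm
    time: float
    event: bool


@dataclass
class SyntheticCohort:
    samples: list[CohortSample]
    predictor: DictBindingPredictor | None = None
    antigen_ids: list[str] = field(default_factory=list)
    presented_truth: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# genome


@dataclass(frozen=True)
class GenomeConfig:
    length: int = 50_000
    n_exons: int = 8
    orf_codons: tuple[int, int] = (60, 160)  # sense codons incl. start, excl. stop
    n_introns: int = 4
    intron_len: tuple[int, int] = (300, 700)
    n_ere: int = 3
    ere_len: tuple[int, int] = (300, 600)
    n_hypervariable: int = 1
    hypervariable_len: tuple[int, int] = (300, 600)
    n_intergenic_tx: int = 2
    intergenic_tx_len: tuple[int, int] = (300, 600)
    # fraction of each region's transcripts flagged tumor_only (first ones)
    tumor_only_fraction: dict[str, float] = field(
        default_factory=lambda: {
            "exon": 0.25,
            "intron": 0.5,
            "intergenic": 1.0,
            "ERE": 1.0,
            "hypervariable": 1.0,
        }
    )

    def validate(self) -> None:
        if self.length <= 0:
            raise ValueError("invalid config: zero-length genome")
        for name in ("n_exons", "n_introns", "n_ere", "n_hypervariable", "n_intergenic_tx"):
            if getattr(self, name) < 1:
                raise ValueError(f"invalid config: {name} must be >= 1")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def simulate_genome(seed: int, config: GenomeConfig = GenomeConfig()) -> SyntheticGenome:
    """Build a genome with non-overlapping annotated regions and planted transcripts.

    Exonic regions carry an ORF (ATG + sense codons + stop; length a
    multiple of 3) written into the genome sequence; other regions keep
    random background. Planted transcripts are exact genome substrings.
    """
    config.validate()
    rng = np.random.default_rng(seed)

    features: list[tuple[str, int]] = []  # (label, length)
    for _ in range(config.n_exons):
        n_codons = int(rng.integers(*config.orf_codons))
        features.append(("exon", 3 * (n_codons + 1)))  # + stop codon
    for _ in range(config.n_introns):
        features.append(("intron", int(rng.integers(*config.intron_len))))
    for _ in range(config.n_ere):
        features.append(("ERE", int(rng.integers(*config.ere_len))))
    for _ in range(config.n_hypervariable):
        features.append(("hypervariable", int(rng.integers(*config.hypervariable_len))))
    order = rng.permutation(len(features))
    features = [features[i] for i in order]

    total = sum(n for _, n in features)
    slack = config.length - total
    if slack < len(features) + 1:
        raise ValueError("invalid config: genome too short for the requested regions")
    gaps = rng.multinomial(slack - (len(features) + 1), [1.0 / (len(features) + 1)] * (len(features) + 1)) + 1

    seq = list(_random_seq(rng, config.length))
    tracks: list[Track] = []
    region_spans: dict[str, list[tuple[int, int]]] = {label: [] for label in REGION_LABELS}
    pos = 0
    for (label, length), gap in zip(features, gaps):
        gap_start, gap_end = pos, pos + int(gap)
        region_spans["intergenic"].append((gap_start, gap_end))
        pos = gap_end
        start, end = pos, pos + length
        if label == "exon":
            orf = ["ATG"]
            orf += [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), length // 3 - 2)]
            orf.append(_STOPS[int(rng.integers(0, 3))])
            seq[start:end] = list("".join(orf))
        tracks.append(
            Track(label=label, start=start, end=end, strand="+",
                  frame=0 if label == "exon" else None,
                  name=f"{label}_{sum(1 for t in tracks if t.label == label) + 1}")
        )
        region_spans[label].append((start, end))
        pos = end
    region_spans["intergenic"].append((pos, config.length))
    for start, end in region_spans["intergenic"]:
        if end > start:
            tracks.append(
                Track(label="intergenic", start=start, end=end, strand="+",
                      name=f"intergenic_{len([t for t in tracks if t.label == 'intergenic']) + 1}")
            )
    sequence = "".join(seq)

    transcripts: list[Transcript] = []

    def plant(region: str, spans: list[tuple[int, int]]) -> None:
        frac = config.tumor_only_fraction.get(region, 0.0)
        n_tumor = int(round(frac * len(spans)))
        for i, (start, end) in enumerate(spans):
            transcripts.append(
                Transcript(
                    id=f"tx_{region}_{i + 1}",
                    sequence=sequence[start:end],
                    region=region,
                    tumor_only=i < n_tumor,
                )
            )

    plant("exon", [(t.start, t.end) for t in tracks if t.label == "exon"])
    plant("intron", [(t.start, t.end) for t in tracks if t.label == "intron"])
    plant("ERE", [(t.start, t.end) for t in tracks if t.label == "ERE"])
    plant("hypervariable", [(t.start, t.end) for t in tracks if t.label == "hypervariable"])
    # intergenic transcripts: substrings of the largest gaps
    gaps_sorted = sorted(
        ((end - start, start, end) for start, end in region_spans["intergenic"]),
        reverse=True,
    )
    ig_spans = []
    for length, start, end in gaps_sorted[: config.n_intergenic_tx]:
        tx_len = min(int(rng.integers(*config.intergenic_tx_len)), length)
        ig_spans.append((start, start + tx_len))
    plant("intergenic", ig_spans)

    tracks.sort(key=lambda t: (t.start, t.end))
    return SyntheticGenome(sequence=sequence, tracks=tracks, planted_transcripts=transcripts)


# ---------------------------------------------------------------------------
# read sets


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    tissue_label: str
    expression: dict[str, float]  # transcript id -> expected read count


@dataclass(frozen=True)
class ReadSimConfig:
    samples: tuple[SampleSpec, ...]
    read_length: int = 100
    substitution_rate: float = 0.0


def simulate_readsets(
    genome: SyntheticGenome, seed: int, config: ReadSimConfig
) -> list[ReadSet]:
    """Draw reads as exact substrings of expressed transcripts.

    Read counts per transcript are Poisson around the configured depth;
    start positions are uniform. Tumor-only transcripts configured for
    an mTEC sample are an invalid config (they would break subtraction
    ground truth). With substitution_rate > 0, bases are substituted
    uniformly at the given per-base rate.
    """
    tx_by_id = {tx.id: tx for tx in genome.planted_transcripts}
    readsets: list[ReadSet] = []
    for idx, spec in enumerate(config.samples):
        rng = np.random.default_rng([seed, idx])
        reads: list[str] = []
        for tx_id in sorted(spec.expression):
            depth = spec.expression[tx_id]
            if depth <= 0:
                continue
            if tx_id not in tx_by_id:
                raise ValueError(f"unknown transcript in config: {tx_id!r}")
            tx = tx_by_id[tx_id]
            if tx.tumor_only and spec.tissue_label == "mTEC":
                raise ValueError(
                    f"invalid config: tumor-only transcript {tx_id!r} assigned to mTEC"
                )
            if len(tx.sequence) < config.read_length:
                raise ValueError(
                    f"transcript {tx_id!r} shorter than read length {config.read_length}"
                )
            n_reads = int(rng.poisson(depth))
            span = len(tx.sequence) - config.read_length + 1
            starts = rng.integers(0, span, n_reads)
            for s in starts:
                reads.append(tx.sequence[s : s + config.read_length])
        if config.substitution_rate > 0:
            reads = [_mutate(r, config.substitution_rate, rng) for r in reads]
        if not reads:
            warnings.warn(f"sample {spec.sample_id!r}: empty read set")
        readsets.append(ReadSet(sample_id=spec.sample_id, tissue_label=spec.tissue_label, reads=reads))
    return readsets


def _mutate(read: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(read))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        arr[hit] = _BASES[rng.integers(0, 4, int(hit.sum()))]
    return "".join(arr)


NORMAL_TISSUES = ("brain", "liver", "lung", "colon", "kidney")


def default_panel(
    genome: SyntheticGenome,
    n_tumor: int = 2,
    n_mtec: int = 3,
    n_testis: int = 2,
    n_per_normal: int = 3,
    n_blood: int = 2,
    n_marrow: int = 2,
    depth: float = 30.0,
    testis_extra: Sequence[str] | None = None,
    tumor_boost: float = 10.0,
) -> ReadSimConfig:
    """The study's tissue panel at desk scale.

    Tumor samples express every planted transcript; mTECs, normal
    tissues, blood and marrow express only shared (non-tumor-only)
    transcripts at the same depth (depth parity is the default because
    relative sequencing depth between tissues is configurable but has
    no stated value). The testis additionally expresses
    ``testis_extra`` transcripts — by default the first tumor-only ERE
    transcript, emulating a cancer-testis expression pattern. One
    shared exonic transcript is overexpressed ``tumor_boost``-fold in
    tumors so the panel contains a tumor-associated (TAA-like) pattern
    as well as tumor-specific ones.
    """
    shared = {tx.id: depth for tx in genome.planted_transcripts if not tx.tumor_only}
    everything = {tx.id: depth for tx in genome.planted_transcripts}
    if tumor_boost and tumor_boost != 1.0:
        boosted = [
            tx.id
            for tx in genome.planted_transcripts
            if tx.region == "exon" and not tx.tumor_only
        ]
        if boosted:
            everything[boosted[-1]] = depth * tumor_boost
    if testis_extra is None:
        ere_tumor = [tx.id for tx in genome.planted_transcripts if tx.region == "ERE" and tx.tumor_only]
        testis_extra = ere_tumor[:1]
    testis = dict(shared)
    for tx_id in testis_extra:
        testis[tx_id] = depth

    samples: list[SampleSpec] = []
    for i in range(n_tumor):
        samples.append(SampleSpec(f"tumor_{i + 1}", "tumor", everything))
    for i in range(n_mtec):
        samples.append(SampleSpec(f"mTEC_{i + 1}", "mTEC", shared))
    for i in range(n_testis):
        samples.append(SampleSpec(f"testis_{i + 1}", "testis", testis))
    for tissue in NORMAL_TISSUES:
        for i in range(n_per_normal):
            samples.append(SampleSpec(f"{tissue}_{i + 1}", tissue, shared))
    for i in range(n_blood):
        samples.append(SampleSpec(f"blood_{i + 1}", "blood", shared))
    for i in range(n_marrow):
        samples.append(SampleSpec(f"marrow_{i + 1}", "marrow", shared))
    return ReadSimConfig(samples=tuple(samples))


# ---------------------------------------------------------------------------
# MS identification lists


@dataclass(frozen=True)
class IdSimConfig:
    n_true: int = 200
    n_decoy: int = 100
    n_false: int = 0  # target-flagged records with null scores (ground-truth false)
    mu_true: float = 3.0
    sigma_true: float = 1.0
    mu_null: float = 0.0
    sigma_null: float = 1.0
    length_range: tuple[int, int] = (8, 11)
    sample_id: str = "tumor_1"


def _candidate_peptides(db, length_range: tuple[int, int]) -> list[str]:
    lo, hi = length_range
    seen: set[str] = set()
    for _, seq in db.entries:
        # J never appears inside a candidate, so linker-spanning windows drop out
        for fragment in seq.split("J"):
            for length in range(lo, hi + 1):
                for i in range(len(fragment) - length + 1):
                    seen.add(fragment[i : i + length])
    return sorted(seen)


def simulate_identifications(db, seed: int, config: IdSimConfig = IdSimConfig()) -> list:
    """Synthetic search-engine output for a protein database.

    True peptides are 8–11-mer substrings of database entries (never
    spanning a JJ linker) with scores from the true distribution;
    decoys are reversed peptides flagged decoy with null scores; false
    targets (optional) are reversed peptides flagged target with null
    scores, giving known true/false labels for FDR calibration.
    """
    from .filtering import PeptideId

    if not db.entries:
        raise ValueError("empty protein database")
    rng = np.random.default_rng(seed)
    pool = _candidate_peptides(db, config.length_range)
    needed = config.n_true + config.n_decoy + config.n_false
    if needed > len(pool):
        raise ValueError(
            f"invalid config: requested {needed} peptides but only {len(pool)} "
            f"distinct substrings are available"
        )
    picks = rng.choice(len(pool), size=needed, replace=False)
    true_peps = [pool[i] for i in picks[: config.n_true]]
    decoy_peps = [pool[i] for i in picks[config.n_true : config.n_true + config.n_decoy]]
    false_peps = [pool[i] for i in picks[config.n_true + config.n_decoy :]]

    ids: list[PeptideId] = []
    for pep, score in zip(true_peps, rng.normal(config.mu_true, config.sigma_true, config.n_true)):
        ids.append(PeptideId(pep, float(score), False, config.sample_id, is_true=True))
    for pep, score in zip(decoy_peps, rng.normal(config.mu_null, config.sigma_null, config.n_decoy)):
        ids.append(PeptideId(pep[::-1], float(score), True, config.sample_id, is_true=False))
    for pep, score in zip(false_peps, rng.normal(config.mu_null, config.sigma_null, config.n_false)):
        ids.append(PeptideId(pep[::-1], float(score), False, config.sample_id, is_true=False))
    return ids


# ---------------------------------------------------------------------------
# cohort


def _default_allele_pool() -> tuple[str, ...]:
    # opaque names echoing HLA nomenclature; the pipeline never parses them
    return tuple(
        f"HLA-{locus}*{i:02d}:01"
        for locus in ("A", "B", "C")
        for i in (1, 2, 3, 11, 24, 26, 30, 68)
    )


@dataclass(frozen=True)
class CohortConfig:
    n_samples: int = 200
    allele_pool: tuple[str, ...] = field(default_factory=_default_allele_pool)
    alleles_per_sample: int = 6
    # MHC I presentation is allele-specific: each peptide is presentable by a
    # small number of allotypes (default one), so a patient presents it only
    # when their genotype carries that allotype (P = 6/24 = 0.25 by default)
    presenting_alleles_per_antigen: int = 1
    expressed_fraction: float = 0.7  # P(antigen has nonzero rphm in a sample)
    log_mean: float = 3.0  # ln-scale location of nonzero rphm (median ~20)
    log_sigma: float = 1.0
    hazard_ratio: float = 1.0  # multiplies hazard when presented count > median
    baseline_hazard: float = 1.0 / 1500.0  # events per day
    censor_time: float = 3000.0  # administrative censoring, days
    expr_cutoff: float = 2.0
    rank_cutoff: float = 2.0

    def validate(self) -> None:
        if self.n_samples < 4:
            raise ValueError("invalid config: n_samples must be >= 4")
        if self.hazard_ratio <= 0:
            raise ValueError("invalid config: hazard_ratio must be > 0")
        if self.alleles_per_sample > len(self.allele_pool):
            raise ValueError("invalid config: alleles_per_sample exceeds the pool")
        if not (1 <= self.presenting_alleles_per_antigen <= len(self.allele_pool)):
            raise ValueError("invalid config: presenting_alleles_per_antigen out of range")


def simulate_cohort(antigens: Sequence, seed: int, config: CohortConfig = CohortConfig()) -> SyntheticCohort:
    """Cohort with HLA genotypes, antigen expression and planted survival.

    Each peptide is assigned ``presenting_alleles_per_antigen`` alleles
    from the pool that present it (rank uniform below the binder
    cutoff); every other allele gets a clearly non-binding rank.
    Survival times are exponential with per-sample hazard
    baseline_hazard * hazard_ratio**I, where I indicates a
    presented-antigen count above the cohort median; hazard_ratio = 1
    yields the null. Administrative censoring at ``censor_time``.
    """
    from .survival import presentation_matrix

    config.validate()
    norm = []
    for a in antigens:
        if hasattr(a, "id"):
            norm.append((a.id, a.peptide))
        else:
            norm.append((a[0], a[1]))
    if not norm:
        raise ValueError("no antigens supplied")
    rng = np.random.default_rng(seed)

    ranks: dict[tuple[str, str], float] = {}
    for _, pep in norm:
        presenting = rng.choice(
            len(config.allele_pool), size=config.presenting_alleles_per_antigen, replace=False
        )
        presenting_set = {config.allele_pool[i] for i in presenting}
        for allele in config.allele_pool:
            if allele in presenting_set:
                ranks[(pep, allele)] = float(rng.uniform(0.0, config.rank_cutoff))
            else:
                ranks[(pep, allele)] = float(
                    rng.uniform(config.rank_cutoff + 3.0, 100.0)
                )
    predictor = DictBindingPredictor(ranks, default=50.0)

    samples: list[CohortSample] = []
    for j in range(config.n_samples):
        alleles = sorted(
            rng.choice(config.allele_pool, size=config.alleles_per_sample, replace=False).tolist()
        )
        expression = {}
        for aid, _ in norm:
            if rng.random() < config.expressed_fraction:
                expression[aid] = float(np.exp(rng.normal(config.log_mean, config.log_sigma)))
            else:
                expression[aid] = 0.0
        samples.append(
            CohortSample(sample_id=f"P{j + 1:04d}", hla_alleles=alleles,
                         expression=expression, time=1.0, event=False)
        )

    cohort = SyntheticCohort(samples=samples, predictor=predictor,
                             antigen_ids=[aid for aid, _ in norm])

    class _Ag:
        __slots__ = ("id", "peptide")

        def __init__(self, aid: str, pep: str):
            self.id, self.peptide = aid, pep

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix = presentation_matrix(
            [_Ag(aid, pep) for aid, pep in norm], cohort, predictor,
            expr_cutoff=config.expr_cutoff, rank_cutoff=config.rank_cutoff,
        )
    counts = matrix.presented_counts()
    med = float(np.median(list(counts.values())))
    for s in samples:
        indicator = counts[s.sample_id] > med
        lam = config.baseline_hazard * (config.hazard_ratio if indicator else 1.0)
        t = float(rng.exponential(1.0 / lam))
        t = max(t, 1e-9)
        s.event = t <= config.censor_time
        s.time = min(t, config.censor_time)
    cohort.presented_truth = counts
    return cohort


# ---------------------------------------------------------------------------
# plain-text emitters


def genome_to_fasta(genome: SyntheticGenome, path: str | Path, name: str = "chrS") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(genome.sequence), 80):
            fh.write(genome.sequence[i : i + 80] + "\n")


def tracks_to_bed(genome: SyntheticGenome, path: str | Path, chrom: str = "chrS") -> None:
    with open(path, "w") as fh:
        for t in genome.tracks:
            fh.write(f"{chrom}\t{t.start}\t{t.end}\t{t.name or t.label}\t0\t{t.strand}\n")


def readset_to_fastq(readset: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, read in enumerate(readset.reads, start=1):
            fh.write(f"@{readset.sample_id}_read{i}\n{read}\n+\n{'I' * len(read)}\n")


def cohort_to_tsv(cohort: SyntheticCohort, path: str | Path) -> None:
    rows = []
    for s in cohort.samples:
        row = {
            "sample_id": s.sample_id,
            "hla_alleles": ";".join(s.hla_alleles),
            "time": s.time,
            "event": int(s.event),
        }
        row.update({aid: s.expression.get(aid, 0.0) for aid in cohort.antigen_ids})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
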