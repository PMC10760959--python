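"""Genomic-origin assignment and the mTSA / aeTSA / TAA decision rules."""

import math

import numpy as np
import pytest

from peptigen.classify import (
    Antigen,
    ClassifierParams,
    GermlineVariantTable,
    assign_origin,
    classify,
)
from peptigen.expression import ExpressionProfile, TissueSummary
from peptigen.synthetic import SyntheticGenome, Track

from conftest import make_readset


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


# --------------------------------------------------------------------------
# origin assignment


class TestAssignOrigin:
    def test_exonic_placement_wins(self, genome):
        exon_tx = next(t for t in genome.planted_transcripts if t.region == "exon")
        cs = exon_tx.sequence[3:30]
        origin, placements = assign_origin(cs, genome)
        assert origin == "exonic"
        assert any(p.origin == "exonic" for p in placements)

    def test_single_ere_placement(self, genome):
        ere_tx = next(t for t in genome.planted_transcripts if t.region == "ERE")
        origin, _ = assign_origin(ere_tx.sequence[10:40], genome)
        assert origin == "ERE"

    def test_hypervariable_excluded(self, genome):
        hv = next(t for t in genome.planted_transcripts if t.region == "hypervariable")
        origin, _ = assign_origin(hv.sequence[5:35], genome)
        assert origin == "excluded-hypervariable"

    def test_unmappable_sequence_discordant(self, genome, rng):
        while True:
            cs = random_seq(rng, 30)
            if cs not in genome.sequence:
                break
        origin, placements = assign_origin(cs, genome)
        assert origin == "excluded-discordant" and placements == []

    def test_max_read_support_breaks_non_exonic_tie(self, rng):
        # same 30-mer planted in an intron and in intergenic space;
        # 3 reads support the intronic copy, 7 the intergenic one
        seq = list(random_seq(rng, 3000))
        segment = random_seq(rng, 30)
        seq[500:530] = segment
        seq[1500:1530] = segment
        genome = SyntheticGenome(
            sequence="".join(seq),
            tracks=[Track(label="intron", start=400, end=800)],
            planted_transcripts=[],
        )
        reads = ["".join(seq[480:580])] * 3 + ["".join(seq[1480:1580])] * 7
        origin, placements = assign_origin(segment, genome, [make_readset(reads)])
        assert origin == "intergenic"
        support = {p.origin: p.reads for p in placements}
        assert support == {"intronic": 3, "intergenic": 7}

    def test_short_sequence_rejected(self, genome):
        with pytest.raises(ValueError):
            assign_origin("ACGTACGT", genome)


# --------------------------------------------------------------------------
# classification


TISSUES = ("tumor", "testis", "mTEC", "blood", "marrow", "brain", "liver", "lung")
NONHEME_NORMALS = ("testis", "brain", "liver", "lung")  # testis special-cased by rule 4


def summarize(values, threshold=8.55, frac=0.10):
    n = len(values)
    above = sum(v > threshold for v in values) / n
    return TissueSummary(
        n_samples=n,
        fraction_above=above,
        mean_log_rphm=sum(math.log10(v + 1) for v in values) / n,
        mean_rphm=sum(values) / n,
        expressing=above > frac,
    )


def make_profile(tissue_values, threshold=8.55, frac=0.10):
    profile = ExpressionProfile(antigen_id="ag", coding_sequence="A" * 27)
    for tissue, values in tissue_values.items():
        profile.group_summary[tissue] = summarize(values, threshold, frac)
    return profile


def antigen(origin="exonic", variants=()):
    return Antigen(
        id="ag", peptide="SAYNTVQTL", coding_sequence="A" * 27,
        origin=origin, variants=tuple(variants),
    )


def expressed_cohort(n=40, frac=1.0):
    return {f"P{i}": (50.0 if i < frac * n else 0.0) for i in range(n)}


def oracle_classify(origin, variants, germline, cohort_values, tissue_values, params):
    """Independent rule-by-rule evaluator used as the classification oracle."""
    if origin in ("excluded-hypervariable", "excluded-discordant"):
        return "rejected"
    prev = sum(v > params.cohort_expr_cutoff for v in cohort_values) / len(cohort_values)
    if prev < params.cohort_prevalence:
        return "rejected"
    if any(v not in germline.variants for v in variants):
        return "mTSA"
    normals = [t for t in tissue_values if t not in (params.tumor_label, params.testis_label)]
    expressing = [
        t
        for t in normals
        if sum(v > params.normal_expr_threshold for v in tissue_values[t])
        / len(tissue_values[t])
        > params.tissue_fraction
    ]
    if not expressing:
        return "aeTSA"
    tumor_mean = sum(tissue_values[params.tumor_label]) / len(tissue_values[params.tumor_label])
    comparators = [
        sum(tissue_values[t]) / len(tissue_values[t])
        for t in normals
        if t not in params.hematopoietic_labels
    ]
    max_normal = max(comparators, default=0.0)
    if tumor_mean > 0 and tumor_mean >= params.taa_fold * max_normal:
        return "TAA"
    return "rejected"


class TestClassifyPaths:
    params = ClassifierParams()
    germline = GermlineVariantTable()

    def _tissue_values(self, tumor=100.0, testis=0.0, normals=0.0, n=10):
        values = {t: [normals] * n for t in TISSUES}
        values["tumor"] = [tumor] * n
        values["testis"] = [testis] * n
        return values

    def _classify(self, origin="exonic", variants=(), cohort=None, tissue_values=None,
                  germline=None, params=None):
        tissue_values = tissue_values or self._tissue_values()
        return classify(
            antigen(origin, variants),
            make_profile(tissue_values),
            germline or self.germline,
            cohort or expressed_cohort(),
            params or self.params,
        )

    def test_tumor_only_is_aetsa(self):
        assert self._classify().label == "aeTSA"

    def test_testis_exception(self):
        call = self._classify(tissue_values=self._tissue_values(testis=500.0))
        assert call.label == "aeTSA"

    def test_mtec_expression_vetoes_aetsa(self):
        values = self._tissue_values()
        values["mTEC"] = [100.0] * 10
        call = self._classify(tissue_values=values)
        assert call.label != "aeTSA"

    def test_excluded_origin_rejected(self):
        call = self._classify(origin="excluded-hypervariable")
        assert call.label == "rejected"
        assert call.trace[0][0] == "origin"

    def test_low_prevalence_rejected(self):
        call = self._classify(cohort=expressed_cohort(frac=0.025))
        assert call.label == "rejected"
        assert any(rule == "cohort-prevalence" for rule, d, _ in call.trace if d == "reject")

    def test_somatic_variant_is_mtsa(self):
        call = self._classify(variants=[(4, "C", "T")])
        assert call.label == "mTSA"

    def test_germline_variant_is_not_mtsa(self):
        germline = GermlineVariantTable(variants={(4, "C", "T")})
        call = self._classify(variants=[(4, "C", "T")], germline=germline)
        assert call.label == "aeTSA"

    def test_overexpressed_tumor_is_taa(self):
        values = self._tissue_values(tumor=400.0, normals=100.0)
        assert self._classify(tissue_values=values).label == "TAA"

    def test_insufficient_fold_rejected(self):
        values = self._tissue_values(tumor=40.0, normals=50.0)
        call = self._classify(tissue_values=values)
        assert call.label == "rejected"
        assert call.trace[-1][0] == "tumor-overexpression"

    def test_exact_ten_percent_edge_not_expressing(self):
        # exactly 1 of 10 brain samples above 8.55: not flagged, still aeTSA
        values = self._tissue_values()
        values["brain"] = [50.0] + [0.0] * 9
        assert self._classify(tissue_values=values).label == "aeTSA"
        values["brain"] = [50.0, 50.0] + [0.0] * 8
        assert self._classify(tissue_values=values).label != "aeTSA"

    def test_trace_replay_idempotent(self):
        call1 = self._classify()
        call2 = self._classify()
        assert call1.label == call2.label and call1.trace == call2.trace


def random_case(rng, params):
    origin = rng.choice(
        ["exonic", "intronic", "intergenic", "ERE", "smRNA",
         "excluded-hypervariable", "excluded-discordant"]
    )
    variants = tuple(
        (int(rng.integers(0, 27)), "A", "G") for _ in range(int(rng.integers(0, 2)))
    )
    germline = GermlineVariantTable(
        variants={(int(rng.integers(0, 27)), "A", "G") for _ in range(3)}
    )
    cohort = {f"P{i}": float(rng.choice([0.0, 1.0, 3.0, 50.0])) for i in range(40)}
    tissue_values = {
        t: [float(v) for v in rng.choice([0.0, 5.0, 8.55, 20.0, 200.0], size=10)]
        for t in TISSUES
    }
    return origin, variants, germline, cohort, tissue_values


@pytest.mark.parametrize("seed", range(4))
def test_classify_matches_oracle_on_random_profiles(seed):
    """classify() agrees with a brute-force rule evaluator on random inputs."""
    rng = np.random.default_rng(seed)
    params = ClassifierParams()
    germ_mismatch = 0
    for _ in range(250):
        origin, variants, germline, cohort, tissue_values = random_case(rng, params)
        call = classify(
            antigen(origin, variants), make_profile(tissue_values),
            germline, cohort, params,
        )
        expected = oracle_classify(
            origin, variants, germline, list(cohort.values()), tissue_values, params
        )
        assert call.label == expected


def test_threshold_monotonicity_aetsa_only_degrades():
    """Lowering the normal-tissue detection threshold can only move calls
    out of aeTSA (to TAA or rejected), never into it."""
    rng = np.random.default_rng(99)
    params_hi = ClassifierParams(normal_expr_threshold=8.55)
    params_lo = ClassifierParams(normal_expr_threshold=2.0)
    for _ in range(200):
        tissue_values = {
            t: [float(v) for v in rng.choice([0.0, 3.0, 5.0, 20.0, 100.0], size=10)]
            for t in TISSUES
        }
        cohort = expressed_cohort()
        call_hi = classify(
            antigen(), make_profile(tissue_values, threshold=8.55),
            GermlineVariantTable(), cohort, params_hi,
        )
        call_lo = classify(
            antigen(), make_profile(tissue_values, threshold=2.0),
            GermlineVariantTable(), cohort, params_lo,
        )
        if call_lo.label == "aeTSA":
            assert call_hi.label == "aeTSA"
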