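"""Ground-truth properties of the four synthetic-data generators."""

import numpy as np
import pytest

from peptigen.filtering import fdr_threshold
from peptigen.kmers import count_kmers
from peptigen.proteome import build_canonical
from peptigen.synthetic import (
    CohortConfig,
    GenomeConfig,
    IdSimConfig,
    ReadSimConfig,
    SampleSpec,
    simulate_cohort,
    simulate_genome,
    simulate_identifications,
    simulate_readsets,
    default_panel,
)

from conftest import SMALL_GENOME

STOPS = {"TAA", "TAG", "TGA"}


class TestGenome:
    def test_deterministic_per_seed(self):
        g1 = simulate_genome(1, SMALL_GENOME)
        g2 = simulate_genome(1, SMALL_GENOME)
        assert g1.sequence == g2.sequence
        assert g1.tracks == g2.tracks
        assert g1.planted_transcripts == g2.planted_transcripts

    def test_different_seeds_differ(self):
        assert simulate_genome(1, SMALL_GENOME).sequence != simulate_genome(2, SMALL_GENOME).sequence

    def test_every_label_has_a_track(self, genome):
        labels = {t.label for t in genome.tracks}
        assert labels == {"exon", "intron", "intergenic", "ERE", "hypervariable"}

    def test_exon_orfs_are_well_formed(self, genome):
        for tx in genome.planted_transcripts:
            if tx.region != "exon":
                continue
            seq = tx.sequence
            assert len(seq) % 3 == 0
            assert seq.startswith("ATG")
            assert seq[-3:] in STOPS
            internal = {seq[i : i + 3] for i in range(3, len(seq) - 3, 3)}
            assert not (internal & STOPS)

    def test_transcripts_are_genome_substrings(self, genome):
        for tx in genome.planted_transcripts:
            assert tx.sequence in genome.sequence

    def test_tracks_do_not_overlap(self, genome):
        spans = sorted((t.start, t.end) for t in genome.tracks)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_zero_length_genome_rejected(self):
        with pytest.raises(ValueError, match="invalid config"):
            simulate_genome(1, GenomeConfig(length=0))

    def test_genome_too_small_for_features_rejected(self):
        with pytest.raises(ValueError):
            simulate_genome(1, GenomeConfig(length=500))


class TestReadsets:
    def _config(self, genome, tumor_depth=50.0, mtec_depth=50.0):
        shared = {t.id: mtec_depth for t in genome.planted_transcripts if not t.tumor_only}
        everything = {t.id: tumor_depth for t in genome.planted_transcripts}
        return ReadSimConfig(
            samples=(
                SampleSpec("tumor_1", "tumor", everything),
                SampleSpec("mTEC_1", "mTEC", shared),
            )
        )

    def test_same_seed_byte_identical(self, genome):
        cfg = self._config(genome)
        a = simulate_readsets(genome, 3, cfg)
        b = simulate_readsets(genome, 3, cfg)
        assert [rs.reads for rs in a] == [rs.reads for rs in b]

    def test_reads_are_transcript_substrings(self, genome):
        for rs in simulate_readsets(genome, 3, self._config(genome)):
            tx_seqs = [t.sequence for t in genome.planted_transcripts]
            for read in rs.reads[:50]:
                assert len(read) == 100
                assert any(read in s for s in tx_seqs)

    def test_tumor_only_kmers_absent_from_mtec(self, genome):
        readsets = simulate_readsets(genome, 3, self._config(genome))
        mtec = next(rs for rs in readsets if rs.tissue_label == "mTEC")
        mtec_table = count_kmers(mtec.reads, k=33)
        for tx in genome.planted_transcripts:
            if not tx.tumor_only:
                continue
            for i in range(len(tx.sequence) - 32):
                assert tx.sequence[i : i + 33] not in mtec_table

    def test_tumor_only_in_mtec_config_rejected(self, genome):
        tumor_only = next(t.id for t in genome.planted_transcripts if t.tumor_only)
        cfg = ReadSimConfig(samples=(SampleSpec("m1", "mTEC", {tumor_only: 10.0}),))
        with pytest.raises(ValueError, match="invalid config"):
            simulate_readsets(genome, 1, cfg)

    def test_depth_doubling_doubles_expected_reads(self, genome):
        tx = next(t for t in genome.planted_transcripts if len(t.sequence) > 150)
        means = []
        for depth in (40.0, 80.0):
            counts = []
            for seed in range(20):
                cfg = ReadSimConfig(samples=(SampleSpec("s", "tumor", {tx.id: depth}),))
                (rs,) = simulate_readsets(genome, seed, cfg)
                counts.append(rs.total_reads)
            means.append(np.mean(counts))
        assert means[1] / means[0] == pytest.approx(2.0, rel=0.10)

    def test_all_zero_depth_warns(self, genome):
        cfg = ReadSimConfig(
            samples=(SampleSpec("s", "tumor", {genome.planted_transcripts[0].id: 0.0}),)
        )
        with pytest.warns(UserWarning, match="empty read set"):
            (rs,) = simulate_readsets(genome, 1, cfg)
        assert rs.total_reads == 0

    def test_default_panel_covers_all_tissue_groups(self, genome):
        cfg = default_panel(genome)
        tissues = {s.tissue_label for s in cfg.samples}
        assert {"tumor", "mTEC", "testis", "blood", "marrow"} <= tissues


@pytest.fixture(scope="module")
def search_db(genome):
    tpm = {t.id: 10.0 for t in genome.planted_transcripts}
    return build_canonical(genome, tpm)


class TestIdentifications:
    def test_no_decoys_all_targets(self, search_db):
        ids = simulate_identifications(search_db, 1, IdSimConfig(n_true=20, n_decoy=0))
        assert all(not p.is_decoy for p in ids)

    def test_true_peptides_are_database_substrings(self, search_db):
        ids = simulate_identifications(search_db, 1, IdSimConfig(n_true=50, n_decoy=20))
        entries = search_db.sequences()
        for p in ids:
            assert 8 <= len(p.sequence) <= 11
            if p.is_true:
                assert any(p.sequence in e for e in entries)
                assert "J" not in p.sequence

    def test_separated_scores_retain_all_targets(self, search_db):
        cfg = IdSimConfig(n_true=100, n_decoy=50, mu_true=100.0, mu_null=0.0,
                          sigma_true=0.1, sigma_null=0.1)
        ids = simulate_identifications(search_db, 2, cfg)
        _, retained = fdr_threshold(ids, 0.01)
        assert len(retained) == 100

    def test_score_means_match_config(self, search_db):
        cfg = IdSimConfig(n_true=100, n_decoy=100, mu_true=4.0, mu_null=1.0)
        true_scores, decoy_scores = [], []
        for seed in range(50):
            for p in simulate_identifications(search_db, seed, cfg):
                (decoy_scores if p.is_decoy else true_scores).append(p.score)
        assert np.mean(true_scores) == pytest.approx(4.0, rel=0.05)
        assert np.mean(decoy_scores) == pytest.approx(1.0, rel=0.05)

    def test_overdrawn_pool_rejected(self, search_db):
        with pytest.raises(ValueError, match="invalid config"):
            simulate_identifications(search_db, 1, IdSimConfig(n_true=10**7))

    def test_deterministic(self, search_db):
        a = simulate_identifications(search_db, 9, IdSimConfig(n_true=30, n_decoy=10))
        b = simulate_identifications(search_db, 9, IdSimConfig(n_true=30, n_decoy=10))
        assert a == b


ANTIGENS = [(f"ag{i}", pep) for i, pep in enumerate(
    ["SAYNTVQTL", "KLWDRTAGY", "MVNPQRSTE", "FGHDEKWYA", "PQKNMVRST", "AEDFGHKLW"]
)]


class TestCohort:
    def test_deterministic(self):
        cfg = CohortConfig(n_samples=4)
        a = simulate_cohort(ANTIGENS, 5, cfg)
        b = simulate_cohort(ANTIGENS, 5, cfg)
        assert [(s.sample_id, s.hla_alleles, s.expression, s.time, s.event)
                for s in a.samples] == [
            (s.sample_id, s.hla_alleles, s.expression, s.time, s.event)
            for s in b.samples
        ]

    def test_structure_invariants(self):
        cohort = simulate_cohort(ANTIGENS, 5, CohortConfig(n_samples=30))
        for s in cohort.samples:
            assert s.time > 0
            assert len(s.hla_alleles) == 6
            assert all(v >= 0 for v in s.expression.values())

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="hazard_ratio"):
            simulate_cohort(ANTIGENS, 1, CohortConfig(hazard_ratio=0.0))
        with pytest.raises(ValueError, match="n_samples"):
            simulate_cohort(ANTIGENS, 1, CohortConfig(n_samples=3))

    def test_hazard_ratio_shifts_high_group_survival(self):
        # strong protective effect: high-presented samples live longer on average
        cfg = CohortConfig(n_samples=300, hazard_ratio=0.2, censor_time=1e9)
        cohort = simulate_cohort(ANTIGENS, 11, cfg)
        counts = cohort.presented_truth
        med = np.median(list(counts.values()))
        high = [s.time for s in cohort.samples if counts[s.sample_id] > med]
        low = [s.time for s in cohort.samples if counts[s.sample_id] <= med]
        assert np.mean(high) > 2 * np.mean(low)
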