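"""End-to-end orchestration: simulate -> build databases -> filter ->
profile -> classify -> present -> survive, with a reproducible manifest.

Each stage reads only the previous stages' in-memory products and the
run config; all randomness derives from the config seed, so rerunning
an identical config reproduces byte-identical outputs and a
hash-identical manifest. Stage timings go to stderr, never into
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from pathlib import Path

import yaml

from . import __version__
from .classify import Antigen, ClassifierParams, GermlineVariantTable, assign_origin, classify, calls_to_tsv
from .config import STAGES, RunConfig
from .expression import profile_antigen, profiles_to_tsv, summaries_to_tsv
from .filtering import fdr_threshold, filter_candidates, resolve_li_variants, write_ids_tsv
from .predictors import MockBindingPredictor
from .proteome import build_canonical, build_cancer_specific, build_ere, build_smrna
from .survival import presentation_matrix, survival_analysis
from .synthetic import (
    cohort_to_tsv,
    default_panel,
    genome_to_fasta,
    readset_to_fastq,
    simulate_cohort,
    simulate_genome,
    simulate_identifications,
    simulate_readsets,
    tracks_to_bed,
)
from .translate import six_frame

log = logging.getLogger("peptigen")

__all__ = ["run_pipeline", "back_map_peptide"]


def _derive_seed(seed: int, stage_index: int) -> int:
    return (seed * 1_000 + stage_index) % (2**31 - 1)


def back_map_peptide(peptide: str, genome) -> tuple[str, str] | None:
    """Find the nucleotide sequence coding a peptide in a planted transcript.

    Searches all six frames of every planted transcript; returns
    (transcript id, coding sequence) in the orientation found, or None
    when the peptide maps to no transcript. Deterministic: transcripts
    are scanned in planting order, frames forward before reverse.
    """
    from .kmers import revcomp

    for tx in genome.planted_transcripts:
        for strand, frame, aa in six_frame(tx.sequence):
            pos = aa.find(peptide)
            if pos == -1:
                continue
            nt = tx.sequence if strand == "+" else revcomp(tx.sequence)
            start = frame + 3 * pos
            return tx.id, nt[start : start + 3 * len(peptide)]
    return None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the enabled stages and write outputs plus a manifest.

    Returns the manifest dict; raises with the failing stage's name on
    any stage error.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    counts: dict[str, int] = {}
    outputs: list[Path] = []
    state: dict = {}

    def enabled(stage: str) -> bool:
        return config.stages.get(stage, True)

    def run_stage(stage: str, fn) -> None:
        if not enabled(stage):
            log.info("stage %s: skipped (disabled)", stage)
            return
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        log.info("stage %s: %.2fs", stage, time.perf_counter() - t0)

    # ---- simulate -------------------------------------------------------
    def stage_simulate() -> None:
        genome = simulate_genome(_derive_seed(config.seed, 0), config.genome)
        panel = default_panel(
            genome,
            n_tumor=config.panel.n_tumor,
            n_mtec=config.panel.n_mtec,
            n_testis=config.panel.n_testis,
            n_per_normal=config.panel.n_per_normal,
            n_blood=config.panel.n_blood,
            n_marrow=config.panel.n_marrow,
            depth=config.panel.depth,
        )
        readsets = simulate_readsets(genome, _derive_seed(config.seed, 1), panel)
        state["genome"] = genome
        state["readsets"] = readsets
        counts["transcripts"] = len(genome.planted_transcripts)
        counts["readsets"] = len(readsets)
        counts["reads_total"] = sum(rs.total_reads for rs in readsets)
        genome_to_fasta(genome, outdir / "genome.fa")
        tracks_to_bed(genome, outdir / "tracks.bed")
        outputs.extend([outdir / "genome.fa", outdir / "tracks.bed"])
        fastq_dir = outdir / "reads"
        fastq_dir.mkdir(exist_ok=True)
        for rs in readsets:
            path = fastq_dir / f"{rs.sample_id}.fastq"
            readset_to_fastq(rs, path)
            outputs.append(path)

    # ---- build databases ------------------------------------------------
    def stage_build_db() -> None:
        genome = state["genome"]
        readsets = state["readsets"]
        tumor = [rs for rs in readsets if rs.tissue_label == "tumor"]
        mtec_reads = [r for rs in readsets if rs.tissue_label == "mTEC" for r in rs.reads]
        tpm = {tx.id: 10.0 for tx in genome.planted_transcripts}
        canonical_db = build_canonical(genome, tpm, variants=())
        ere_db = build_ere(tumor[0].reads)
        smrna_db = build_smrna(tumor[0].reads)
        cancer_db = build_cancer_specific(tumor[0].reads, mtec_reads)
        combined = canonical_db.concat(ere_db).concat(smrna_db).concat(cancer_db, name="search")
        state["search_db"] = combined
        for db in (canonical_db, ere_db, smrna_db, cancer_db):
            path = outdir / f"db_{db.name}.fa"
            db.to_fasta(path)
            outputs.append(path)
            counts[f"db_{db.name}_entries"] = len(db)

    # ---- identification filtering --------------------------------------
    def stage_filter() -> None:
        db = state["search_db"]
        ids = simulate_identifications(db, _derive_seed(config.seed, 2), config.identifications)
        counts["identifications"] = len(ids)
        threshold, retained = fdr_threshold(ids, th.fdr)
        counts["fdr_retained"] = len(retained)
        predictor = MockBindingPredictor()
        # the tumor sample's HLA genotype: first alleles of the cohort pool
        alleles = list(config.cohort.allele_pool[: config.cohort.alleles_per_sample])
        sample_alleles = {config.identifications.sample_id: alleles}
        candidates = filter_candidates(
            retained, predictor, sample_alleles,
            min_len=th.min_len, max_len=th.max_len, rank_cutoff=th.rank_cutoff,
        )
        counts["candidates"] = len(candidates)
        non_candidates = {p.sequence for p in retained} - {p.sequence for p in candidates}
        genome = state["genome"]
        tumor_rs = [rs for rs in state["readsets"] if rs.tissue_label == "tumor"]

        def expr(seq: str, sample_id: str) -> float:
            hit = back_map_peptide(seq, genome)
            if hit is None:
                return 0.0
            from .expression import rphm as _rphm

            return _rphm(hit[1], tumor_rs[0])

        def region(seq: str) -> str:
            hit = back_map_peptide(seq, genome)
            if hit is None:
                return "excluded-discordant"
            origin, _ = assign_origin(hit[1], genome)
            return origin

        resolved = resolve_li_variants(candidates, non_candidates, expr, region)
        counts["li_resolved"] = len(resolved)
        state["retained_ids"] = resolved
        write_ids_tsv(resolved, outdir / "identifications.tsv")
        outputs.append(outdir / "identifications.tsv")

    # ---- antigens + expression profiling -------------------------------
    def stage_profile() -> None:
        genome = state["genome"]
        readsets = state["readsets"]
        tumor_rs = [rs for rs in readsets if rs.tissue_label == "tumor"]
        antigens: list[Antigen] = []
        seen: set[str] = set()
        for p in state["retained_ids"]:
            if p.sequence in seen:
                continue
            seen.add(p.sequence)
            hit = back_map_peptide(p.sequence, genome)
            if hit is None:
                continue
            _, cs = hit
            origin, _ = assign_origin(cs, genome, tumor_rs)
            antigens.append(
                Antigen(id=f"ag_{len(antigens) + 1:04d}", peptide=p.sequence,
                        coding_sequence=cs, origin=origin)
            )
        counts["antigens"] = len(antigens)
        profiles = {
            a.id: profile_antigen(
                a.id, a.coding_sequence, readsets,
                threshold=th.rphm_threshold, tissue_fraction=th.tissue_fraction,
            )
            for a in antigens
        }
        state["antigens"] = antigens
        state["profiles"] = profiles
        profiles_to_tsv(profiles.values(), outdir / "expression_profiles.tsv")
        summaries_to_tsv(profiles.values(), outdir / "expression_summaries.tsv")
        outputs.extend([outdir / "expression_profiles.tsv", outdir / "expression_summaries.tsv"])

    # ---- cohort + classification ---------------------------------------
    def stage_classify() -> None:
        antigens = state["antigens"]
        if not antigens:
            raise ValueError("no antigens to classify")
        cohort = simulate_cohort(antigens, _derive_seed(config.seed, 3), config.cohort)
        state["cohort"] = cohort
        cohort_to_tsv(cohort, outdir / "cohort.tsv")
        outputs.append(outdir / "cohort.tsv")
        params = ClassifierParams(
            normal_expr_threshold=th.rphm_threshold,
            tissue_fraction=th.tissue_fraction,
            cohort_prevalence=th.prevalence,
            cohort_expr_cutoff=th.cohort_expr_cutoff,
            taa_fold=th.taa_fold,
        )
        germline = GermlineVariantTable()
        calls = []
        for a in antigens:
            cohort_expr = {s.sample_id: s.expression.get(a.id, 0.0) for s in cohort.samples}
            calls.append(classify(a, state["profiles"][a.id], germline, cohort_expr, params))
        state["calls"] = calls
        for label in ("mTSA", "aeTSA", "TAA", "rejected"):
            counts[f"calls_{label}"] = sum(1 for c in calls if c.label == label)
        calls_to_tsv(calls, {a.id: a for a in antigens}, outdir / "antigen_calls.tsv")
        outputs.append(outdir / "antigen_calls.tsv")

    # ---- presentation ---------------------------------------------------
    def stage_present() -> None:
        cohort = state["cohort"]
        kept = [a for a, c in zip(state["antigens"], state["calls"]) if c.label != "rejected"]
        if not kept:
            kept = state["antigens"]  # fall back to all candidates
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            matrix = presentation_matrix(
                kept, cohort, cohort.predictor,
                expr_cutoff=th.cohort_expr_cutoff, rank_cutoff=th.rank_cutoff,
            )
        state["matrix"] = matrix
        counts["presented_cells"] = int((matrix.states == 2).sum())
        matrix.to_tsv(outdir / "presentation_matrix.tsv")
        outputs.append(outdir / "presentation_matrix.tsv")

    # ---- survival -------------------------------------------------------
    def stage_survive() -> None:
        cohort = state["cohort"]
        matrix = state["matrix"]
        times = {s.sample_id: s.time for s in cohort.samples}
        events = {s.sample_id: s.event for s in cohort.samples}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            presented = survival_analysis(matrix.presented_counts(), times, events)
            expr_only = survival_analysis(matrix.expressed_not_presented_counts(), times, events)
        result = {"presented": presented, "expression_only_control": expr_only}
        state["survival"] = result
        with open(outdir / "survival.json", "w") as fh:
            json.dump(result, fh, indent=2, sort_keys=True)
        outputs.append(outdir / "survival.json")

    stage_fns = {
        "simulate": stage_simulate,
        "build_db": stage_build_db,
        "filter": stage_filter,
        "profile": stage_profile,
        "classify": stage_classify,
        "present": stage_present,
        "survive": stage_survive,
    }
    for stage in STAGES:
        run_stage(stage, stage_fns[stage])

    config_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config_yaml.encode()).hexdigest(),
        "stages_run": [s for s in STAGES if enabled(s)],
        "record_counts": counts,
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(outputs)},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
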