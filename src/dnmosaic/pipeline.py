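"""End-to-end driver: simulate (or load) a cohort, then discover, phase,
test, classify, and estimate recurrence, writing every stage's table."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io
from .config import PipelineConfig
from .discovery import call_dnms, candidates_to_frame, detect_clusters, titv_summary
from .mosaic import (call_mosaics, classify_postzygotic, control_noise_median,
                     wgs_altread_screen)
from .phasing import phase_cohort
from .recurrence import (classify_origins, enrichment_summary,
                         group_comparisons, recurrence_report)
from .simulate import Cohort, simulate_cohort, trio_samples, write_cohort

log = logging.getLogger("dnmosaic")


@dataclass
class PipelineResult:
    dnms: pd.DataFrame
    clusters: list
    titv: pd.DataFrame
    phased: pd.DataFrame
    phasing_summary: dict
    mosaic_calls: pd.DataFrame
    mosaic_summary: dict
    postzygotic: pd.DataFrame
    classification: pd.DataFrame
    classification_summary: dict
    report: object
    enrichment: dict
    comparisons: dict
    wgs_screen: dict
    summary: dict


def child_deep_vaf(counts: pd.DataFrame) -> dict[str, float]:
    """Primary-replicate child blood VAF per variant (its own trio)."""
    out = {}
    for r in counts[(counts.tissue == "child_blood")
                    & (counts.replicate == "primary")].itertuples():
        two = r.ref_count + r.alt_count
        out.setdefault(r.variant_key, {})[r.trio] = (r.alt_count / two
                                                     if two else math.nan)
    # keep only the focal-trio measurement: resolved later against trio_id
    return out


def postzygotic_table(phased: pd.DataFrame, counts: pd.DataFrame,
                      config: PipelineConfig,
                      repeat_flags: dict[str, bool] | None = None
                      ) -> pd.DataFrame:
    """Apply the two-metric child-mosaic rule to every phased DNM."""
    vafs = child_deep_vaf(counts)
    repeat_flags = repeat_flags or {}
    rows = []
    for row in phased.itertuples():
        smmip = vafs.get(row.variant_key, {}).get(row.trio_id, math.nan)
        eligible, pz = classify_postzygotic(
            smmip, row.haplotype_specific_vaf, row.origin_hap_depth,
            row.variant_type, row.parent_of_origin,
            repeat_flag=repeat_flags.get(row.variant_key, False),
            thresholds=config.thresholds)
        rows.append({"variant_key": row.variant_key, "trio_id": row.trio_id,
                     "child_smmip_vaf": smmip,
                     "haplotype_specific_vaf": row.haplotype_specific_vaf,
                     "origin_hap_depth": row.origin_hap_depth,
                     "eligible": eligible, "postzygotic": pz})
    return pd.DataFrame(rows, columns=[
        "variant_key", "trio_id", "child_smmip_vaf", "haplotype_specific_vaf",
        "origin_hap_depth", "eligible", "postzygotic"])


def discover_from_cohort(cohort: Cohort, config: PipelineConfig,
                         workdir: Path) -> tuple[pd.DataFrame, dict]:
    """Write the cohort VCFs and run trio filtering through the VCF reader,
    so discovery exercises the same path as external data."""
    paths = write_cohort(cohort, workdir)
    families = io.read_ped(paths["cohort.ped"])
    frames, summaries = [], {}
    for trio_id in sorted(cohort.vcfs):
        trio = {m: trio_samples(trio_id)[m] for m in ("child", "father", "mother")}
        stream = io.read_trio_vcf(paths[f"{trio_id}.vcf"], trio)
        records = [r for r in stream if r is not None]
        cands, summary = call_dnms(records, trio_id, config.thresholds)
        frames.append(candidates_to_frame(cands))
        summaries[trio_id] = summary
        log.info("%s: %d records in, %d DNM candidates", trio_id,
                 summary["records_seen"], summary["pass"])
    assert set(families) == set(summaries)
    dnms = pd.concat(frames, ignore_index=True)
    return dnms, summaries


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 cohort: Cohort | None = None) -> PipelineResult:
    """Execute every stage on a synthetic (or supplied) cohort.

    Writes each stage's table under ``outdir`` and returns all in-memory
    results plus a combined summary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    if cohort is None:
        sim = config.simulation
        if sim.seed != config.seed:
            sim = type(sim)(**{**sim.__dict__, "seed": config.seed})
        cohort = simulate_cohort(sim)

    dnms, discovery_summaries = discover_from_cohort(cohort, config,
                                                     outdir / "cohort")
    clusters = detect_clusters(dnms, gap_bp=thr.cluster_gap_bp)
    titv = titv_summary(dnms, clusters)

    phased, phasing_summary = phase_cohort(
        cohort.tagged_reads, dnms,
        min_alt_reads=thr.min_alt_reads,
        max_minor_fraction=thr.max_minor_fraction)

    calls, mosaic_summary = call_mosaics(cohort.counts, phased, thr)
    pz = postzygotic_table(phased, cohort.counts, config)
    classification, class_summary = classify_origins(calls, pz, phased)

    report = recurrence_report(phased, calls, thr, seed=config.seed)

    blood_conf = calls[(calls.tissue.isin(["father_blood", "mother_blood"]))
                       & calls.confirmed]
    blood_keys = set(blood_conf.variant_key)
    pat = phased[phased.parent_of_origin == "paternal"]
    mat = phased[phased.parent_of_origin == "maternal"]
    enrichment = enrichment_summary(
        len(blood_keys & set(mat.variant_key)), len(mat),
        len(blood_keys & set(pat.variant_key)), len(pat))

    sperm_conf = set(calls[(calls.tissue == "father_sperm")
                           & calls.confirmed].variant_key)
    shared = sorted(blood_keys & sperm_conf & set(pat.variant_key))
    sperm_vaf = {r.variant_key: r.vaf_point_estimate
                 for r in calls[calls.tissue == "father_sperm"].itertuples()}
    blood_vaf = {r.variant_key: r.vaf_point_estimate
                 for r in calls[calls.tissue == "father_blood"].itertuples()}
    sperm_only = sorted((sperm_conf - blood_keys) & set(pat.variant_key))
    comparisons = group_comparisons(
        [blood_vaf[k] for k in shared], [sperm_vaf[k] for k in shared],
        [sperm_vaf[k] for k in sperm_only])

    screen = wgs_altread_screen(cohort.wgs_pileup, blood_keys,
                                min_alt=thr.wgs_screen_min_alt)

    trios = cohort.counts.trio.unique()
    noise = (control_noise_median(
        cohort.counts, dict(zip(dnms.variant_key, dnms.trio_id)))
        if len(trios) > 1 else math.nan)

    summary = {
        "per_trio_dnms": {t: s["pass"] for t, s in discovery_summaries.items()},
        "mean_dnms_per_trio": dnms.groupby("trio_id").size().mean(),
        "n_clusters": len(clusters),
        "phasing_rate": phasing_summary["cohort"]["phasing_rate"],
        "paternal_fraction": phasing_summary["cohort"]["paternal_fraction"],
        "median_control_vaf": noise,
        "n_tests": mosaic_summary["n_tests_executed"],
        "bonferroni_threshold": mosaic_summary["threshold"],
        "mosaic_per_trio": mosaic_summary["per_trio"],
        "origin_counts": class_summary["counts"],
        "recurrence": report.as_dict(),
        "enrichment": enrichment,
        "comparisons": comparisons,
        "wgs_screen": {k: v for k, v in screen.items()
                       if k != "candidate_keys"},
    }

    seed, thr_dict = config.seed, thr.as_dict()
    io.write_tsv(dnms, outdir / "dnms.tsv", seed, thr_dict)
    io.write_tsv(phased, outdir / "phased.tsv", seed, thr_dict)
    io.write_tsv(calls, outdir / "mosaic_calls.tsv", seed, thr_dict)
    io.write_tsv(pz, outdir / "postzygotic.tsv", seed, thr_dict)
    io.write_tsv(classification, outdir / "classification.tsv", seed, thr_dict)
    io.write_tsv(titv, outdir / "titv.tsv", seed, thr_dict)
    io.write_json(summary, outdir / "summary.json", seed, thr_dict)

    return PipelineResult(
        dnms=dnms, clusters=clusters, titv=titv, phased=phased,
        phasing_summary=phasing_summary, mosaic_calls=calls,
        mosaic_summary=mosaic_summary, postzygotic=pz,
        classification=classification, classification_summary=class_summary,
        report=report, enrichment=enrichment, comparisons=comparisons,
        wgs_screen=screen, summary=summary)
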