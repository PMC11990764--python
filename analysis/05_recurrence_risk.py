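#!/usr/bin/env python
"""Classify mutational origins and estimate recurrence risk.

Each assessed DNM gets one category (parental pre-PGC blood mosaic,
sperm-confined post-PGC mosaic, child postzygotic, one-off); the paternal
recurrence risk is the zero-imputed mean sperm VAF, extrapolated maternally
by the paternal/maternal count ratio.  Also reports the maternal-vs-paternal
blood-mosaicism enrichment and the sperm/blood VAF comparisons.
Writes results/classification.tsv, results/recurrence.json.
"""

import json

from dnmosaic import io
from dnmosaic.config import PipelineConfig
from dnmosaic.recurrence import (adjusted_events_per_child, classify_origins,
                                 enrichment_summary, group_comparisons,
                                 recurrence_report)


def main() -> None:
    config = PipelineConfig()
    phased = io.read_tsv("results/phased.tsv")
    calls = io.read_tsv("results/mosaic_calls.tsv")
    pz = io.read_tsv("results/postzygotic.tsv")

    table, summary = classify_origins(calls, pz, phased)
    io.write_tsv(table, "results/classification.tsv")
    print("origin categories:", json.dumps(summary["counts"]))

    report = recurrence_report(phased, calls, config.thresholds)
    print(f"RR_pat = {report.rr_pat:.3%} "
          f"(95% CI {report.rr_pat_ci[0]:.3%}-{report.rr_pat_ci[1]:.3%}), "
          f"raw {report.rr_pat_raw:.3%}")
    print(f"alpha = {report.alpha_ratio:.2f}  RR_mat = {report.rr_mat:.3%}  "
          f"RR_overall = {report.rr_overall:.3%}")

    blood_keys = set(calls[(calls.tissue.isin(["father_blood", "mother_blood"]))
                           & calls.confirmed].variant_key)
    pat = phased[phased.parent_of_origin == "paternal"]
    mat = phased[phased.parent_of_origin == "maternal"]
    enrich = enrichment_summary(
        len(blood_keys & set(mat.variant_key)), len(mat),
        len(blood_keys & set(pat.variant_key)), len(pat))
    print(f"blood-mosaic enrichment maternal/paternal: ratio "
          f"{enrich['rate_ratio']:.2f}, Fisher p {enrich['p_value']:.4f}")

    n_children = phased.trio_id.nunique()
    n_assessed = int((table.category != "unassessed").sum())
    pre_pgc = summary["counts"].get("pre_pgc", 0)
    post_pgc = summary["counts"].get("post_pgc_confined", 0)
    adj_blood = adjusted_events_per_child(pre_pgc, n_children,
                                          len(table), n_assessed)
    adj_sperm = adjusted_events_per_child(post_pgc, n_children,
                                          len(table), n_assessed)
    print(f"adjusted events/child: blood-detected "
          f"{adj_blood['adjusted_rate']:.2f}, sperm-only "
          f"{adj_sperm['adjusted_rate']:.2f}")

    sperm_vaf = {r.variant_key: r.vaf_point_estimate
                 for r in calls[calls.tissue == "father_sperm"].itertuples()}
    blood_vaf = {r.variant_key: r.vaf_point_estimate
                 for r in calls[calls.tissue == "father_blood"].itertuples()}
    sperm_conf = set(calls[(calls.tissue == "father_sperm")
                           & calls.confirmed].variant_key)
    shared = sorted(blood_keys & sperm_conf & set(pat.variant_key))
    only = sorted((sperm_conf - blood_keys) & set(pat.variant_key))
    comp = group_comparisons([blood_vaf[k] for k in shared],
                             [sperm_vaf[k] for k in shared],
                             [sperm_vaf[k] for k in only])
    print("sperm vs blood comparisons:", json.dumps(comp, default=float))

    io.write_json({"recurrence": report.as_dict(), "enrichment": enrich,
                   "adjusted_events": {"blood": adj_blood, "sperm_only": adj_sperm},
                   "comparisons": comp},
                  "results/recurrence.json",
                  thresholds=config.thresholds.as_dict())


if __name__ == "__main__":
    main()
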