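#!/usr/bin/env python
"""Test every DNM for parental mosaicism in the deep-count data.

Haplotype-coherent plan (paternal: father blood + sperm; maternal: mother
blood; unphased: all three), exact conditional rate test against the pooled
16-sample control noise, Bonferroni threshold over the executed tests, and
confirmation on the independent replicate.  Also applies the two-metric
child-postzygotic rule and the parental-WGS alt-read screen.
Writes results/mosaic_calls.tsv, results/postzygotic.tsv,
results/screen.json.
"""

import json

from dnmosaic import io
from dnmosaic.config import PipelineConfig
from dnmosaic.mosaic import call_mosaics, control_noise_median, wgs_altread_screen
from dnmosaic.pipeline import postzygotic_table


def main() -> None:
    config = PipelineConfig()
    counts = io.read_tsv("results/cohort/deep_counts.tsv")
    phased = io.read_tsv("results/phased.tsv")

    noise = control_noise_median(
        counts, dict(zip(phased.variant_key, phased.trio_id)))
    print(f"median control VAF {noise:.3%}")

    calls, summary = call_mosaics(counts, phased, config.thresholds)
    io.write_tsv(calls, "results/mosaic_calls.tsv",
                 thresholds=config.thresholds.as_dict())
    print(f"{summary['n_tests_executed']} tests "
          f"(threshold {summary['threshold']:.2e}), per-trio confirmed:")
    print(json.dumps(summary["per_trio"], indent=1))

    pz = postzygotic_table(phased, counts, config)
    io.write_tsv(pz, "results/postzygotic.tsv")
    print(f"postzygotic: {int(pz.postzygotic.sum())} calls among "
          f"{int(pz.eligible.sum())} eligible variants")

    wgs = io.read_tsv("results/cohort/wgs_pileup.tsv")
    blood_keys = set(calls[(calls.tissue.isin(["father_blood", "mother_blood"]))
                           & calls.confirmed].variant_key)
    screen = wgs_altread_screen(wgs, blood_keys,
                                min_alt=config.thresholds.wgs_screen_min_alt)
    io.write_json({"screen": {k: v for k, v in screen.items()
                              if k != "candidate_keys"}},
                  "results/screen.json")
    print(f"WGS screen: recall {screen['recall']:.1%}, "
          f"precision {screen['precision']:.1%}")


if __name__ == "__main__":
    main()
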