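#!/usr/bin/env python
"""Assign parent of origin from haplotype-tagged long reads.

For each DNM the tagged-read evidence gives alt-bearing read counts per
parental haplotype; a variant is phased when at least 3 tagged alt reads
agree (minority share <= 10%).  The haplotype-specific VAF (alt fraction on
the mutated haplotype) is carried along for postzygotic detection.
Writes results/phased.tsv.
"""

import json

from dnmosaic import io
from dnmosaic.phasing import phase_cohort


def main() -> None:
    dnms = io.read_tsv("results/dnms.tsv")
    evidence = io.read_tsv("results/cohort/tagged_reads.tsv")
    phased, summary = phase_cohort(evidence, dnms)
    io.write_tsv(phased, "results/phased.tsv")
    c = summary["cohort"]
    print(f"phased {c['n_phased']}/{c['n']} DNMs "
          f"({c['phasing_rate']:.1%}), paternal fraction "
          f"{c['paternal_fraction']:.1%}")
    print(json.dumps(summary["per_trio"], indent=1, default=float))


if __name__ == "__main__":
    main()
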