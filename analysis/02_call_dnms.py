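#!/usr/bin/env python
"""Call de novo mutations from the trio VCFs.

Applies the six-filter cascade (trio genotype pattern, DP > 20, GQ > 29,
child VAF > 0.25, biallelic-fraction guard, 4x parent-child VAF shift) to
each trio, then annotates 20 kb mutational clusters and the clustered vs
non-clustered Ti/Tv contrast.  Writes results/dnms.tsv, results/titv.tsv.
"""

import pandas as pd

from dnmosaic import io
from dnmosaic.config import Thresholds
from dnmosaic.discovery import (call_dnms, candidates_to_frame,
                                detect_clusters, titv_summary)
from dnmosaic.simulate import trio_samples


def main() -> None:
    thresholds = Thresholds()
    families = io.read_ped("results/cohort/cohort.ped")
    frames = []
    for trio_id in sorted(families):
        records = [r for r in io.read_trio_vcf(
            f"results/cohort/{trio_id}.vcf", families[trio_id])
            if r is not None]
        cands, summary = call_dnms(records, trio_id, thresholds)
        frames.append(candidates_to_frame(cands))
        print(f"{trio_id}: {summary['pass']} DNMs "
              f"({summary['snv']} SNV / {summary['indel']} indel) "
              f"from {summary['records_seen']} sites")
    dnms = pd.concat(frames, ignore_index=True)
    clusters = detect_clusters(dnms, gap_bp=thresholds.cluster_gap_bp)
    titv = titv_summary(dnms, clusters)
    io.write_tsv(dnms, "results/dnms.tsv", thresholds=thresholds.as_dict())
    io.write_tsv(titv, "results/titv.tsv")
    print(f"total {len(dnms)} DNMs, {len(clusters)} clusters "
          f"(sizes {[c.size for c in clusters]})")
    print(titv.to_string(index=False))


if __name__ == "__main__":
    main()
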