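# Methods

## Model and procedure

The pipeline treats a de novo mutation (DNM) as a variant heterozygous in a
child and absent from both parents' constitutional genomes, and asks where
in the parental germline (or the child's early embryo) it arose:

* **pre-PGC parental mosaic** — arose before primordial-germ-cell
  specification; detectable in the parent's blood (and, paternally, in
  sperm). Transmissible at the mosaic fraction.
* **post-PGC confined germline mosaic** — arose in the germline after PGC
  specification; paternally detectable in sperm only.
* **child postzygotic** — arose in the child after fertilisation;
  no recurrence risk for siblings.
* **one-off** — no mosaic signal anywhere; recurrence risk below the
  detection floor.

Detection proceeds in four stages (discovery → phasing → deep-count
testing → classification/recurrence), each a pure function over tabular
inputs so stages can be run, tested, and substituted independently.

## Statistical choices

**Rate test.** The test of a tissue's alt rate against pooled control noise
is the exact conditional comparison of two Poisson rates: conditional on
k = alt_test + alt_ctrl, the test count is Binomial(k, n_t/(n_t+n_c)) under
the null of equal rates, and the p-value is the upper tail at the observed
count. This form is exact, conservative, and — unlike a plug-in Poisson
tail with λ = n_t·alt_ctrl/n_c — remains well defined when the controls
carry zero alt reads (the plug-in tail returns p = 0 for any observation
there). The plug-in variant is kept behind `Thresholds.naive_poisson` for
sensitivity analysis only.

**Multiplicity.** Bonferroni over the haplotype-coherent plan: 2 tests per
paternally phased variant, 1 per maternal, 3 per unphased. N is the count
of tests actually executed (planned tests without usable counts are
skipped and logged), not a fixed constant. Confirmation applies the same
test and the same threshold to the independent replicate; "confirmed"
requires significance in both. The family-wise error of the whole
procedure is verified by simulation (1000 null batches of 637 tests) in
the acceptance suite.

**Postzygotic rule.** Child mosaics need concordant deviation of two
metrics: deep-count child VAF < 0.45 (from the constitutional 0.5) and
haplotype-specific VAF < 0.9 (from 1.0), with eligibility restricted to
SNVs with a determined origin, ≥ 4 reads on the mutated haplotype, and
capture arms outside repeats. Requiring both metrics guards against each
assay's individual noise.

**Recurrence.** RR_pat = mean sperm VAF over assessed paternally phased
variants with zero imputed below significance; RR_pat_raw keeps raw VAFs
and therefore bounds RR_pat from above. The 95% CI is a normal
approximation on the per-variant vector (zeros included) — chosen for
transparency on a sparse, heavy-tailed vector; a seeded percentile
bootstrap (10,000 resamples) is available via `Thresholds.bootstrap_ci`
and agrees closely in tests. The maternal extrapolation RR_mat = RR_pat·α
(α = paternal/maternal phased counts) rests on the biological symmetry of
peri-gonadal mosaic loads between the sexes; its CI is the paternal CI
scaled by α, so it inherits the paternal estimate's uncertainty but not
the uncertainty in α itself. The detectability adjustment for per-child
event rates, (events/children)·(total/assessed), assumes assessed variants
are a random subset of all DNMs and is labelled approximate in the output.

**Enrichment and group comparisons.** The maternal-vs-paternal
blood-mosaicism contrast uses the two-sided Fisher exact test in the
point-probability convention and reports the ratio of proportions (not the
odds ratio). Sperm-vs-blood VAFs of shared mosaics use the exact paired
Wilcoxon signed-rank test; sperm-only vs shared sperm VAFs use the exact
Mann-Whitney U.

## Synthetic cohort generator

Defaults emulate the study conditions: 5 trios, Poisson(85.6) DNMs per
trio, paternal probability 0.8, deduplicated deep-count depths 5557×
(child blood), 8314× (parental blood), 5755× (sperm), global noise VAF
2.2e-4, 40× parental WGS, ~30× haplotagged long reads with 10% untagged.
Injected mosaics per trio: 1–4 parental blood mosaics (VAF 0.35–14.7%,
log-uniform; paternal ones get sperm VAF = blood VAF × U(1,3), since shared
mosaics are usually at least as abundant in sperm), 1–2 sperm-confined
paternal mosaics (VAF from 0.24%), and 0–2 child postzygotic SNVs (child
VAF 0.10–0.40). DNM counts are Poisson because that is the standard null
for mutation counts; positions are uniform within chromosomes weighted by
length; substitutions draw transitions at 2/3 (Ti/Tv ≈ 2).

Depths are Poisson around the tissue mean, with an optional gamma
multiplier (`depth_dispersion`, CV, default 0) because real capture depth
is over-dispersed in a design-specific way we do not model; likewise
`noise_dispersion` can impose per-site noise heterogeneity (default off —
the default noise model is a single global rate).

The generator emits the *discovered* call set: genotype fields of truth
DNMs are sampled conditional on passing the filters, because the truth
table plays the role of the curated high-confidence DNM list that feeds
phasing and deep sequencing. Consequences for interpretation: pipeline
recall/precision of 1.0 on synthetic VCFs exercises the filter logic and
plumbing, not robustness to borderline calls, alignment artifacts,
repeat-mediated capture bias, UMI errors, or index hopping — none of which
are simulated. Filter behaviour at and across each threshold is tested on
directly constructed records instead.

## Numerical details

* Strict inequalities follow the filter definitions (DP > 20 means 21
  passes, 20 fails; child VAF exactly 0.25 fails).
* The VAF-shift rule passes when a parent's VAF is exactly 0 (no division),
  which is what lets parental mosaics reach the deep-count stage.
* A Ti/Tv stratum with zero transversions reports NaN, not infinity.
* Haplotype-specific VAF with zero origin-haplotype reads is NaN with
  depth 0; callers treat it as unphasable evidence.
* An empty test plan yields a NaN Bonferroni threshold and no calls.
* Cluster chaining uses single linkage with gap ≤ 20,000 bp on POS
  (1-based VCF coordinates throughout); singletons are not clusters.
* Seeds: every artifact of the generator derives from an independent
  child stream of the configured seed, so artifacts are individually and
  jointly reproducible; identical seeds give byte-identical files.

## Problem sizes in the test and acceptance runs

The default cohort (5 trios, ~428 DNMs, full study depths) simulates and
runs end to end in a few seconds, so the suite uses it directly; the
null-calibration check uses 1000 replicates of the full 637-test burden,
and parameter-recovery uses 200 independent cohorts at the study's
paternal-set size (~244 assessed paternal variants per cohort).

## Known limitations

* Parental age effects on DNM counts and the per-position control noise
  model of real pipelines (beyond the optional gamma heterogeneity) are
  not simulated.
* The maternal extrapolation inherits the strong symmetry assumption; no
  oocyte data exists to test it here.
* The CI on RR_mat ignores sampling error in α.
* Phasing consumes tagged-read evidence; generating that evidence from raw
  alignments (read-backed phasing itself) is upstream of this package.
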