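"""Parental and child mosaicism detection from deep targeted counts.

The central statistic is a one-sided comparison of two Poisson rates: the
alt-read rate of a test tissue (a parent's blood or sperm) against pooled
sequencing noise estimated from every sample of the other families.  The
exact conditional formulation is used: given k = alt_test + alt_ctrl total
alt reads, alt_test ~ Binomial(k, n_test/(n_test+n_ctrl)) under the null of
equal rates, and the p-value is the upper tail at the observed alt_test.
This stays well defined when the controls carry zero alt reads, where a
plug-in Poisson tail would call any alt observation infinitely significant;
the plug-in variant is retained behind a flag for sensitivity analysis.

Multiplicity is controlled with a Bonferroni correction over the
haplotype-coherent test plan: paternally phased variants are tested in
father blood and sperm only, maternal ones in mother blood only, unphased
ones in all three tissues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import Thresholds

#: tissues interrogated per parent-of-origin label
PLAN_TISSUES = {
    "paternal": ("father_blood", "father_sperm"),
    "maternal": ("mother_blood",),
    "unphased": ("father_blood", "father_sperm", "mother_blood"),
    "conflict": ("father_blood", "father_sperm", "mother_blood"),
}


def rate_test(alt_test: int, total_test: int, alt_ctrl: int, total_ctrl: int,
              naive_poisson: bool = False) -> float:
    """One-sided p-value for 'test alt rate > control alt rate'.

    Exact conditional form (default): p = P(X >= alt_test) with
    X ~ Binomial(alt_test + alt_ctrl, total_test / (total_test + total_ctrl)).
    Naive form: upper Poisson tail at lambda = total_test * alt_ctrl/total_ctrl.
    """
    if min(alt_test, alt_ctrl) < 0:
        raise ValueError("negative counts")
    if total_test <= 0 or total_ctrl <= 0:
        raise ValueError("totals must be positive")
    if naive_poisson:
        lam = total_test * alt_ctrl / total_ctrl
        return float(stats.poisson.sf(alt_test - 1, lam))
    k = alt_test + alt_ctrl
    if k == 0:
        return 1.0
    q = total_test / (total_test + total_ctrl)
    return float(stats.binom.sf(alt_test - 1, k, q))


def rate_test_vectorized(alt_test, total_test, alt_ctrl, total_ctrl) -> np.ndarray:
    """Array form of the exact conditional test (null simulations)."""
    alt_test = np.asarray(alt_test)
    k = alt_test + np.asarray(alt_ctrl)
    q = np.asarray(total_test) / (np.asarray(total_test) + np.asarray(total_ctrl))
    p = stats.binom.sf(alt_test - 1, k, q)
    return np.where(k == 0, 1.0, p)


@dataclass
class ControlPool:
    """Pooled noise counts per variant from all non-focal families."""

    alt: dict[str, int]
    total: dict[str, int]
    n_samples: dict[str, int]
    median_vaf: float


def pool_controls(counts: pd.DataFrame, focal_trio: str,
                  replicate: str = "primary",
                  focal_variants=None) -> ControlPool:
    """Sum alt and two-allele totals over every sample of the other families.

    The pool is only a valid noise model for the focal family's own variants
    (every other family is a non-carrier there); the reported median control
    VAF is therefore restricted to ``focal_variants`` when given.  Rows with
    ref+alt == 0 at a position are treated as missing for that control
    sample.  Reads supporting third alleles (other_count) never enter the
    totals — the two-allele convention.
    """
    ctrl = counts[(counts.trio != focal_trio) & (counts.replicate == replicate)]
    if ctrl.empty or ctrl.trio.nunique() == 0:
        raise ValueError("no control families available")
    ctrl = ctrl.assign(two_total=ctrl.ref_count + ctrl.alt_count)
    ctrl = ctrl[ctrl.two_total > 0]
    g = ctrl.groupby("variant_key")
    alt = g.alt_count.sum().to_dict()
    total = g.two_total.sum().to_dict()
    n_samples = g["sample"].nunique().to_dict()
    keys = alt.keys() if focal_variants is None else \
        [k for k in focal_variants if k in alt]
    vafs = np.array([alt[k] / total[k] for k in keys if total[k] > 0])
    median_vaf = float(np.median(vafs)) if len(vafs) else math.nan
    return ControlPool(alt=alt, total=total, n_samples=n_samples,
                       median_vaf=median_vaf)


def control_noise_median(counts: pd.DataFrame,
                         variant_trio_map: dict[str, str]) -> float:
    """Median pooled-control VAF across positions, each variant measured
    against the pool that excludes its own family."""
    vafs = []
    for trio in sorted(set(variant_trio_map.values())):
        focal = [k for k, t in variant_trio_map.items() if t == trio]
        pool = pool_controls(counts, trio, focal_variants=focal)
        vafs.extend(pool.alt[k] / pool.total[k]
                    for k in focal if pool.total.get(k, 0) > 0)
    return float(np.median(vafs)) if vafs else math.nan


def enumerate_tests(phased: pd.DataFrame, alpha: float = 0.05
                    ) -> tuple[pd.DataFrame, int, float]:
    """Build the haplotype-coherent test plan.

    Returns (plan frame with variant_key / trio_id / tissue, total test
    count N, Bonferroni threshold alpha/N; threshold is NaN when N == 0).
    """
    rows = []
    for row in phased.itertuples():
        for tissue in PLAN_TISSUES[row.parent_of_origin]:
            rows.append({"variant_key": row.variant_key,
                         "trio_id": row.trio_id, "tissue": tissue})
    plan = pd.DataFrame(rows, columns=["variant_key", "trio_id", "tissue"])
    n_tests = len(plan)
    threshold = alpha / n_tests if n_tests else math.nan
    return plan, n_tests, threshold


def call_mosaics(counts: pd.DataFrame, phased: pd.DataFrame,
                 thresholds: Thresholds = Thresholds()) -> tuple[pd.DataFrame, dict]:
    """Run the planned rate tests and the confirmation replicate.

    A variant-tissue pair is a candidate when the primary-replicate test is
    significant at the Bonferroni threshold, and confirmed when the
    independent confirmation replicate is significant at the same threshold.
    N for the Bonferroni correction is the number of tests actually executed
    (planned tests without usable counts are skipped and logged).
    VAF point estimates come from the primary replicate; a pooled-replicate
    estimate is reported alongside.
    """
    plan, _, _ = enumerate_tests(phased, thresholds.alpha)

    lookup: dict[tuple, tuple[int, int]] = {}
    for r in counts.itertuples():
        two = r.ref_count + r.alt_count
        lookup[(r.variant_key, r.trio, r.tissue, r.replicate)] = (r.alt_count, two)

    pools = {(trio, rep): pool_controls(counts, trio, rep)
             for trio in plan.trio_id.unique()
             for rep in ("primary", "confirmation")}

    executed, skipped = [], []
    for row in plan.itertuples():
        key = (row.variant_key, row.trio_id, row.tissue, "primary")
        if key not in lookup or lookup[key][1] == 0:
            skipped.append((row.variant_key, row.trio_id, row.tissue))
            continue
        executed.append(row)
    n_tests = len(executed)
    threshold = thresholds.alpha / n_tests if n_tests else math.nan

    out = []
    for row in executed:
        results = {}
        for rep in ("primary", "confirmation"):
            obs = lookup.get((row.variant_key, row.trio_id, row.tissue, rep))
            pool = pools[(row.trio_id, rep)]
            c_alt = pool.alt.get(row.variant_key, 0)
            c_tot = pool.total.get(row.variant_key, 0)
            if obs is None or obs[1] == 0 or c_tot == 0:
                results[rep] = (math.nan, math.nan, False)
                continue
            alt, tot = obs
            p = rate_test(alt, tot, c_alt, c_tot,
                          naive_poisson=thresholds.naive_poisson)
            results[rep] = (p, alt / tot, n_tests > 0 and p < threshold)
        p1, vaf1, sig1 = results["primary"]
        p2, vaf2, sig2 = results["confirmation"]
        alt1, tot1 = lookup[(row.variant_key, row.trio_id, row.tissue, "primary")]
        obs2 = lookup.get((row.variant_key, row.trio_id, row.tissue, "confirmation"))
        if obs2 and (tot1 + obs2[1]) > 0:
            vaf_pooled = (alt1 + obs2[0]) / (tot1 + obs2[1])
        else:
            vaf_pooled = vaf1
        out.append({
            "variant_key": row.variant_key, "trio_id": row.trio_id,
            "tissue": row.tissue, "alt_primary": alt1, "total_primary": tot1,
            "p_primary": p1, "p_confirmation": p2,
            "significant": bool(sig1), "confirmed": bool(sig1 and sig2),
            "vaf_point_estimate": vaf1, "vaf_pooled_estimate": vaf_pooled,
            "n_tests_total": n_tests, "threshold": threshold})
    calls = pd.DataFrame(out, columns=[
        "variant_key", "trio_id", "tissue", "alt_primary", "total_primary",
        "p_primary", "p_confirmation", "significant", "confirmed",
        "vaf_point_estimate", "vaf_pooled_estimate", "n_tests_total",
        "threshold"])

    summary = {"n_tests_planned": len(plan), "n_tests_executed": n_tests,
               "n_skipped": len(skipped), "threshold": threshold,
               "per_trio": {}}
    if len(calls):
        conf = calls[calls.confirmed]
        for trio, sub in conf.groupby("trio_id"):
            blood = set(sub[sub.tissue.isin(["father_blood", "mother_blood"])]
                        .variant_key)
            sperm = set(sub[sub.tissue == "father_sperm"].variant_key)
            summary["per_trio"][trio] = {
                "blood_detected": len(blood),
                "sperm_only": len(sperm - blood)}
    return calls, summary


def classify_postzygotic(child_smmip_vaf: float, hap_specific_vaf: float,
                         origin_hap_depth: int, variant_type: str,
                         parent_of_origin: str, repeat_flag: bool = False,
                         thresholds: Thresholds = Thresholds()
                         ) -> tuple[bool, bool]:
    """Child postzygotic-mosaic call from the two concordant VAF metrics.

    Eligible: SNV with a determined parental origin, at least 4 long reads on
    the mutated haplotype, and capture arms not embedded in a repeat.
    Postzygotic: eligible and deep-count VAF < 0.45 and haplotype-specific
    VAF < 0.9 — both metrics must deviate from the constitutional
    expectation (0.5 and 1.0 respectively).
    """
    eligible = (variant_type == "SNV"
                and parent_of_origin in ("paternal", "maternal")
                and origin_hap_depth >= thresholds.postzygotic_min_hap_depth
                and not repeat_flag
                and not (child_smmip_vaf is None or math.isnan(child_smmip_vaf))
                and not math.isnan(hap_specific_vaf))
    if not eligible:
        return False, False
    postzygotic = (child_smmip_vaf < thresholds.postzygotic_max_smmip_vaf
                   and hap_specific_vaf < thresholds.postzygotic_max_hap_vaf)
    return True, postzygotic


def wgs_altread_screen(wgs_pileup: pd.DataFrame, true_mosaic_keys: set[str],
                       min_alt: int = 1) -> dict:
    """Screen parental standard-depth WGS for mosaic evidence.

    A variant is a candidate when either parent shows >= ``min_alt`` alt
    reads.  Recall is the fraction of deep-sequencing-confirmed blood mosaics
    among candidates; precision is the fraction of candidates that are
    confirmed mosaics (NaN when there are no candidates).
    """
    flagged = wgs_pileup[wgs_pileup.alt_count >= min_alt]
    candidates = set(flagged.variant_key)
    tp = candidates & true_mosaic_keys
    recall = len(tp) / len(true_mosaic_keys) if true_mosaic_keys else math.nan
    precision = len(tp) / len(candidates) if candidates else math.nan
    return {"n_candidates": len(candidates), "n_true": len(true_mosaic_keys),
            "n_true_positive": len(tp), "recall": recall,
            "precision": precision, "min_alt": min_alt,
            "candidate_keys": sorted(candidates)}


def screen_metrics(n_detected: int, n_true: int, n_candidates: int) -> dict:
    """Recall / precision from confusion counts of an alt-read screen."""
    return {
        "recall": n_detected / n_true if n_true else math.nan,
        "precision": n_detected / n_candidates if n_candidates else math.nan,
    }


# ---------------------------------------------------------------------------
# calibration helpers


def simulate_null_batches(n_batches: int, n_tests: int, noise_vaf: float,
                          test_depth: int, ctrl_depth: int, alpha: float,
                          rng: np.random.Generator) -> float:
    """Family-wise error of the Bonferroni-corrected procedure under the null.

    Draws ``n_batches`` independent experiments of ``n_tests`` tests each,
    with alt counts Binomial(depth, noise) in both test and pooled-control
    arms, and returns the fraction of batches with any p below
    alpha / n_tests.
    """
    shape = (n_batches, n_tests)
    alt_t = rng.binomial(test_depth, noise_vaf, size=shape)
    alt_c = rng.binomial(ctrl_depth, noise_vaf, size=shape)
    p = rate_test_vectorized(alt_t, test_depth, alt_c, ctrl_depth)
    return float(np.mean((p < alpha / n_tests).any(axis=1)))


def detection_power(vaf: float, test_depth: int, noise_vaf: float,
                    ctrl_depth: int, threshold: float) -> float:
    """Exact single-test power against a mosaic of the given VAF.

    Sums over the pooled-control alt-count distribution; for each control
    outcome finds the smallest significant test count (the p-value is
    nonincreasing in alt_test) and accumulates the alternative's upper tail.
    """
    q = test_depth / (test_depth + ctrl_depth)
    ctrl = stats.binom(ctrl_depth, noise_vaf)
    j_max = int(ctrl.ppf(1 - 1e-12)) + 2
    power = 0.0
    for j in range(j_max + 1):
        pj = ctrl.pmf(j)
        if pj < 1e-15:
            continue
        c = 0
        while stats.binom.sf(c - 1, c + j, q) >= threshold:
            c += 1
            if c > test_depth:
                break
        power += pj * stats.binom.sf(c - 1, test_depth, vaf + noise_vaf)
    return float(power)
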