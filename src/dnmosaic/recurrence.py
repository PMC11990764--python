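"""Mutational-origin classification and recurrence-risk estimation.

The recurrence risk of a paternally phased de novo variant is taken to be
its sperm VAF — the fraction of mutant gametes.  Cohort-level estimates:

* ``RR_pat``: mean sperm VAF over assessed paternally phased variants, with
  zero imputed for variants that never reached significance (their VAF is
  below the detection floor);
* ``RR_pat_raw``: the same mean using raw measured VAFs for non-significant
  variants (upper-bound companion, so RR_pat <= RR_pat_raw);
* ``RR_mat`` = RR_pat x alpha, where alpha is the paternal/maternal phased
  count ratio — peri-gonadal mosaic loads are expected to be symmetric
  between the sexes, so the maternal per-variant risk scales with the
  inverse of the paternal excess;
* ``RR_overall`` = p_pat*RR_pat + p_mat*RR_mat over the phased fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import Thresholds

CATEGORIES = ("pre_pgc", "post_pgc_confined", "child_postzygotic",
              "one_off", "unassessed")


def classify_origins(mosaic_calls: pd.DataFrame,
                     postzygotic: pd.DataFrame,
                     phased: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Assign each DNM exactly one mutational-origin category.

    * ``pre_pgc``: confirmed mosaic in a parent's blood (pre-germline
      specification — the mutation is in the parent's soma and germline);
    * ``post_pgc_confined``: confirmed sperm mosaic with non-significant
      blood (confined germline mosaicism);
    * ``child_postzygotic``: the variant arose in the child after
      fertilization (two-metric VAF call);
    * ``one_off``: assessed, no mosaic evidence anywhere;
    * ``unassessed``: no usable deep-count tests for the variant.

    Parental-mosaic evidence takes precedence over a child-postzygotic call
    (parental mosaicism is necessarily pre-zygotic); the conflict is
    reported in the summary.
    """
    by_variant: dict[str, dict[str, pd.Series]] = {}
    for row in mosaic_calls.itertuples():
        by_variant.setdefault(row.variant_key, {})[row.tissue] = row
    pz_calls = {row.variant_key: bool(row.postzygotic)
                for row in postzygotic.itertuples()} if len(postzygotic) else {}

    rows, conflicts = [], []
    for row in phased.itertuples():
        key = row.variant_key
        tests = by_variant.get(key, {})
        blood = [t for name, t in tests.items()
                 if name in ("father_blood", "mother_blood")]
        sperm = tests.get("father_sperm")
        blood_confirmed = [t for t in blood if t.confirmed]
        sperm_confirmed = sperm is not None and sperm.confirmed
        is_pz = pz_calls.get(key, False)
        evidence = []
        if not tests:
            category = "unassessed"
        elif blood_confirmed:
            category = "pre_pgc"
            evidence = [t.tissue for t in blood_confirmed]
            if sperm_confirmed:
                evidence.append("father_sperm")
            if is_pz:
                conflicts.append(key)
        elif sperm_confirmed:
            category = "post_pgc_confined"
            evidence = ["father_sperm"]
            if is_pz:
                conflicts.append(key)
        elif is_pz:
            category = "child_postzygotic"
            evidence = ["haplotype_specific_vaf", "child_deep_vaf"]
        else:
            category = "one_off"
        rows.append({"variant_key": key, "trio_id": row.trio_id,
                     "parent_of_origin": row.parent_of_origin,
                     "category": category,
                     "evidence": ";".join(evidence)})
    table = pd.DataFrame(rows, columns=["variant_key", "trio_id",
                                        "parent_of_origin", "category",
                                        "evidence"])
    summary = {"counts": table.category.value_counts().to_dict(),
               "per_trio": {t: s.category.value_counts().to_dict()
                            for t, s in table.groupby("trio_id")},
               "precedence_conflicts": conflicts}
    return table, summary


@dataclass
class RecurrenceReport:
    rr_pat: float
    rr_pat_ci: tuple[float, float]
    rr_pat_raw: float
    rr_pat_raw_ci: tuple[float, float]
    n_paternal_assessed: int
    n_significant: int
    mean_significant_vaf: float
    alpha_ratio: float
    rr_mat: float
    rr_mat_ci: tuple[float, float]
    rr_overall: float
    rr_overall_ci: tuple[float, float]
    p_pat: float
    p_mat: float
    high_risk_keys: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "RR_pat": self.rr_pat, "RR_pat_CI": list(self.rr_pat_ci),
            "RR_pat_raw": self.rr_pat_raw,
            "RR_pat_raw_CI": list(self.rr_pat_raw_ci),
            "n_paternal_assessed": self.n_paternal_assessed,
            "n_significant": self.n_significant,
            "mean_significant_vaf": self.mean_significant_vaf,
            "alpha_ratio": self.alpha_ratio,
            "RR_mat": self.rr_mat, "RR_mat_CI": list(self.rr_mat_ci),
            "RR_overall": self.rr_overall,
            "RR_overall_CI": list(self.rr_overall_ci),
            "p_pat": self.p_pat, "p_mat": self.p_mat,
            "high_risk_variants": self.high_risk_keys,
        }


def _mean_ci(values: np.ndarray, bootstrap: bool = False,
             n_bootstrap: int = 10_000, seed: int = 0
             ) -> tuple[float, tuple[float, float]]:
    """Mean with 95% CI: normal approximation by default, percentile
    bootstrap behind a flag.  Degenerate (constant) input gives a point CI."""
    mean = float(np.mean(values))
    if len(values) < 2 or np.ptp(values) == 0:
        return mean, (mean, mean)
    if bootstrap:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(values), size=(n_bootstrap, len(values)))
        means = values[idx].mean(axis=1)
        lo, hi = np.percentile(means, [2.5, 97.5])
        return mean, (float(lo), float(hi))
    se = float(np.std(values, ddof=1) / math.sqrt(len(values)))
    return mean, (max(mean - 1.96 * se, 0.0), mean + 1.96 * se)


def paternal_recurrence(sperm_vafs: np.ndarray, significant: np.ndarray,
                        keys: list[str] | None = None,
                        thresholds: Thresholds = Thresholds(),
                        seed: int = 0) -> dict:
    """Sperm-VAF-based recurrence estimate for paternally phased variants.

    ``sperm_vafs`` are raw measured VAFs per assessed paternal variant;
    ``significant`` marks which reached significance in the sperm test.
    RR_pat zero-imputes non-significant variants, RR_pat_raw keeps them raw.
    """
    sperm_vafs = np.asarray(sperm_vafs, dtype=float)
    significant = np.asarray(significant, dtype=bool)
    if sperm_vafs.size == 0:
        raise ValueError("no assessed paternally phased variants")
    imputed = np.where(significant, sperm_vafs, 0.0)
    rr, rr_ci = _mean_ci(imputed, thresholds.bootstrap_ci,
                         thresholds.n_bootstrap, seed)
    rr_raw, rr_raw_ci = _mean_ci(sperm_vafs, thresholds.bootstrap_ci,
                                 thresholds.n_bootstrap, seed + 1)
    high = significant & (sperm_vafs > thresholds.high_risk_vaf)
    high_keys = ([k for k, h in zip(keys, high) if h] if keys is not None
                 else [str(i) for i in np.flatnonzero(high)])
    n_sig = int(significant.sum())
    return {
        "rr_pat": rr, "rr_pat_ci": rr_ci,
        "rr_pat_raw": rr_raw, "rr_pat_raw_ci": rr_raw_ci,
        "n_assessed": int(sperm_vafs.size), "n_significant": n_sig,
        "mean_significant_vaf": float(sperm_vafs[significant].mean())
                                if n_sig else 0.0,
        "high_risk_keys": high_keys,
    }


def maternal_and_overall(rr_pat: float, rr_pat_ci: tuple[float, float],
                         n_paternal_phased: int, n_maternal_phased: int) -> dict:
    """Extrapolate the maternal and overall risk from the paternal estimate.

    alpha = paternal/maternal phased count ratio; RR_mat = RR_pat * alpha
    (CI scaled identically); RR_overall weights the two by the phased
    fractions, which reduces algebraically to RR_pat * (p_pat + p_mat*alpha).
    """
    if n_maternal_phased <= 0:
        return {"alpha_ratio": math.nan, "rr_mat": math.nan,
                "rr_mat_ci": (math.nan, math.nan), "rr_overall": math.nan,
                "rr_overall_ci": (math.nan, math.nan),
                "p_pat": math.nan, "p_mat": math.nan,
                "warning": "zero maternal phased count"}
    alpha = n_paternal_phased / n_maternal_phased
    n = n_paternal_phased + n_maternal_phased
    p_pat, p_mat = n_paternal_phased / n, n_maternal_phased / n
    rr_mat = rr_pat * alpha
    rr_mat_ci = (rr_pat_ci[0] * alpha, rr_pat_ci[1] * alpha)
    w = p_pat + p_mat * alpha
    return {"alpha_ratio": alpha, "rr_mat": rr_mat, "rr_mat_ci": rr_mat_ci,
            "rr_overall": rr_pat * w,
            "rr_overall_ci": (rr_pat_ci[0] * w, rr_pat_ci[1] * w),
            "p_pat": p_pat, "p_mat": p_mat}


def recurrence_report(phased: pd.DataFrame, mosaic_calls: pd.DataFrame,
                      thresholds: Thresholds = Thresholds(),
                      seed: int = 0) -> RecurrenceReport:
    """Full cohort recurrence estimate from phased DNMs and mosaic calls."""
    sperm = mosaic_calls[mosaic_calls.tissue == "father_sperm"]
    sperm_by_key = {r.variant_key: r for r in sperm.itertuples()}
    paternal = phased[phased.parent_of_origin == "paternal"]
    keys, vafs, sigs = [], [], []
    for row in paternal.itertuples():
        call = sperm_by_key.get(row.variant_key)
        if call is None:
            continue
        keys.append(row.variant_key)
        vafs.append(call.vaf_point_estimate)
        sigs.append(bool(call.confirmed))
    pat = paternal_recurrence(np.array(vafs), np.array(sigs, dtype=bool),
                              keys=keys, thresholds=thresholds, seed=seed)
    n_pat = int((phased.parent_of_origin == "paternal").sum())
    n_mat = int((phased.parent_of_origin == "maternal").sum())
    ext = maternal_and_overall(pat["rr_pat"], pat["rr_pat_ci"], n_pat, n_mat)
    return RecurrenceReport(
        rr_pat=pat["rr_pat"], rr_pat_ci=pat["rr_pat_ci"],
        rr_pat_raw=pat["rr_pat_raw"], rr_pat_raw_ci=pat["rr_pat_raw_ci"],
        n_paternal_assessed=pat["n_assessed"],
        n_significant=pat["n_significant"],
        mean_significant_vaf=pat["mean_significant_vaf"],
        alpha_ratio=ext["alpha_ratio"], rr_mat=ext["rr_mat"],
        rr_mat_ci=ext["rr_mat_ci"], rr_overall=ext["rr_overall"],
        rr_overall_ci=ext["rr_overall_ci"],
        p_pat=ext["p_pat"], p_mat=ext["p_mat"],
        high_risk_keys=pat["high_risk_keys"])


def adjusted_events_per_child(n_events: int, n_children: int,
                              n_total_dnms: int, n_assessed: int) -> dict:
    """Per-child mosaic event rate adjusted for assessability.

    adjusted = (events / children) * (total DNMs / assessed DNMs), an
    approximation that assumes assessed variants are a random subset.  The
    95% CI is exact Poisson on the observed count, scaled identically.
    """
    if not (0 < n_assessed <= n_total_dnms):
        raise ValueError("assessed fraction must lie in (0, 1]")
    scale = n_total_dnms / n_assessed / n_children
    if n_events > 0:
        lo = stats.chi2.ppf(0.025, 2 * n_events) / 2
    else:
        lo = 0.0
    hi = stats.chi2.ppf(0.975, 2 * (n_events + 1)) / 2
    return {"observed": n_events, "adjusted_rate": n_events * scale,
            "ci": (lo * scale, hi * scale)}


def enrichment_summary(n_mosaic_mat: int, n_mat: int,
                       n_mosaic_pat: int, n_pat: int) -> dict:
    """Maternal vs paternal blood-mosaicism enrichment.

    Two-sided Fisher exact test (point-probability convention: the p-value
    sums all tables as or less probable than the observed one) on the 2x2
    table, plus the ratio of mosaic proportions.
    """
    table = [[n_mosaic_mat, n_mat - n_mosaic_mat],
             [n_mosaic_pat, n_pat - n_mosaic_pat]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    prop_mat = n_mosaic_mat / n_mat if n_mat else math.nan
    prop_pat = n_mosaic_pat / n_pat if n_pat else math.nan
    ratio = prop_mat / prop_pat if prop_pat else math.nan
    return {"table": table, "p_value": float(p), "rate_ratio": ratio,
            "prop_maternal": prop_mat, "prop_paternal": prop_pat}


def group_comparisons(shared_blood_vafs: np.ndarray,
                      shared_sperm_vafs: np.ndarray,
                      sperm_only_vafs: np.ndarray) -> dict:
    """VAF comparisons among paternal mosaics.

    Paired exact Wilcoxon signed-rank: sperm vs blood VAF of mosaics seen in
    both tissues.  Exact Mann-Whitney U: sperm VAFs of sperm-confined vs
    shared mosaics.
    """
    blood = np.asarray(shared_blood_vafs, dtype=float)
    sperm = np.asarray(shared_sperm_vafs, dtype=float)
    out: dict = {}
    if len(blood):
        diffs = sperm - blood
        out["median_difference"] = float(np.median(diffs))
        if np.all(diffs == 0):
            out["wilcoxon_p"] = 1.0
            out["warning"] = "all paired differences are zero"
        else:
            res = stats.wilcoxon(sperm, blood, alternative="two-sided",
                                 method="exact")
            out["wilcoxon_p"] = float(res.pvalue)
    only = np.asarray(sperm_only_vafs, dtype=float)
    if len(only) and len(sperm):
        res = stats.mannwhitneyu(only, sperm, alternative="two-sided",
                                 method="exact")
        out["mannwhitney_p"] = float(res.pvalue)
        out["median_sperm_only"] = float(np.median(only))
        out["median_shared_sperm"] = float(np.median(sperm))
    return out
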