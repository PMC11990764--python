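"""Origin classification and recurrence-risk estimation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dnmosaic.config import Thresholds
from dnmosaic.recurrence import (adjusted_events_per_child, classify_origins,
                                 enrichment_summary, group_comparisons,
                                 maternal_and_overall, paternal_recurrence,
                                 recurrence_report)


def call_row(key, tissue, confirmed, significant=None, vaf=0.0):
    return {"variant_key": key, "trio_id": "trio1", "tissue": tissue,
            "p_primary": 1e-9 if confirmed else 0.5,
            "significant": confirmed if significant is None else significant,
            "confirmed": confirmed, "vaf_point_estimate": vaf}


def phased_frame(keys_origins):
    return pd.DataFrame([{"variant_key": k, "trio_id": "trio1",
                          "parent_of_origin": o} for k, o in keys_origins])


def pz_frame(rows):
    return pd.DataFrame([{"variant_key": k, "postzygotic": pz}
                         for k, pz in rows],
                        columns=["variant_key", "postzygotic"])


class TestClassifyOrigins:
    def test_confirmed_blood_mosaic_is_pre_pgc(self):
        calls = pd.DataFrame([call_row("v1", "father_blood", True, vaf=0.05),
                              call_row("v1", "father_sperm", True, vaf=0.08)])
        table, _ = classify_origins(calls, pz_frame([]),
                                    phased_frame([("v1", "paternal")]))
        assert table.category.tolist() == ["pre_pgc"]

    def test_sperm_only_is_post_pgc_confined(self):
        calls = pd.DataFrame([call_row("v1", "father_blood", False),
                              call_row("v1", "father_sperm", True, vaf=0.01)])
        table, _ = classify_origins(calls, pz_frame([]),
                                    phased_frame([("v1", "paternal")]))
        assert table.category.tolist() == ["post_pgc_confined"]

    def test_no_evidence_is_one_off(self):
        calls = pd.DataFrame([call_row("v1", "father_blood", False),
                              call_row("v1", "father_sperm", False)])
        table, _ = classify_origins(calls, pz_frame([]),
                                    phased_frame([("v1", "paternal")]))
        assert table.category.tolist() == ["one_off"]

    def test_no_tests_is_unassessed(self):
        calls = pd.DataFrame(columns=["variant_key", "trio_id", "tissue",
                                      "p_primary", "significant", "confirmed",
                                      "vaf_point_estimate"])
        table, _ = classify_origins(calls, pz_frame([]),
                                    phased_frame([("v1", "paternal")]))
        assert table.category.tolist() == ["unassessed"]

    def test_parental_mosaic_outranks_postzygotic_with_warning(self):
        calls = pd.DataFrame([call_row("v1", "mother_blood", True, vaf=0.03)])
        table, summary = classify_origins(calls, pz_frame([("v1", True)]),
                                          phased_frame([("v1", "maternal")]))
        assert table.category.tolist() == ["pre_pgc"]
        assert summary["precedence_conflicts"] == ["v1"]

    def test_partition_is_exhaustive_and_exclusive(self, small_result):
        table = small_result.classification
        assert len(table) == len(small_result.phased)
        assert table.variant_key.is_unique
        counts = small_result.classification_summary["counts"]
        assert sum(counts.values()) == len(table)

    def test_end_to_end_classification_matches_truth(self, small_cohort,
                                                     small_result):
        # clear-margin cohort: every injected category must be recovered
        truth = small_cohort.truth.set_index("variant_key")
        table = small_result.classification.set_index("variant_key")
        mapping = {"pre_pgc_blood": "pre_pgc",
                   "post_pgc_sperm_only": "post_pgc_confined",
                   "child_postzygotic": "child_postzygotic",
                   "one_off": "one_off"}
        for key, row in table.iterrows():
            expected = mapping[truth.loc[key, "origin_category"]]
            assert row.category == expected, key


class TestPaternalRecurrence:
    def test_printed_cohort_arithmetic(self):
        # 14 significant sperm mosaics with mean VAF 4.7% among 244 assessed
        vafs = np.zeros(244)
        vafs[:14] = 0.047
        sig = vafs > 0
        out = paternal_recurrence(vafs, sig)
        assert out["rr_pat"] * 100 == pytest.approx(0.27, abs=0.005)

    def test_all_zero_gives_degenerate_ci(self):
        out = paternal_recurrence(np.zeros(10), np.zeros(10, dtype=bool))
        assert out["rr_pat"] == 0.0
        assert out["rr_pat_ci"] == (0.0, 0.0)

    def test_zero_imputation_never_exceeds_raw(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 60))
            vafs = rng.uniform(0, 0.2, size=n)
            sig = rng.random(n) < 0.3
            out = paternal_recurrence(vafs, sig)
            assert out["rr_pat"] <= out["rr_pat_raw"] + 1e-15

    def test_high_risk_stratum_uses_one_percent_cutoff(self):
        vafs = np.array([0.05, 0.008, 0.0, 0.2])
        sig = np.array([True, True, False, False])
        out = paternal_recurrence(vafs, sig, keys=["a", "b", "c", "d"])
        assert out["high_risk_keys"] == ["a"]   # significant AND > 1%

    def test_empty_input_is_fatal(self):
        with pytest.raises(ValueError):
            paternal_recurrence(np.array([]), np.array([], dtype=bool))

    def test_bootstrap_ci_close_to_normal_ci(self):
        vafs = np.zeros(244)
        vafs[:14] = np.linspace(0.01, 0.15, 14)
        sig = vafs > 0
        normal = paternal_recurrence(vafs, sig)
        boot = paternal_recurrence(vafs, sig,
                                   thresholds=Thresholds(bootstrap_ci=True),
                                   seed=3)
        assert boot["rr_pat"] == normal["rr_pat"]
        assert boot["rr_pat_ci"][1] == pytest.approx(normal["rr_pat_ci"][1],
                                                     rel=0.25)


class TestMaternalAndOverall:
    def test_alpha_scaling(self):
        out = maternal_and_overall(0.0025, (0.001, 0.004), 240, 60)
        assert out["alpha_ratio"] == 4.0
        assert out["rr_mat"] == pytest.approx(0.01)

    def test_overall_identity(self, rng):
        # RR_overall = RR_pat * (p_pat + p_mat * alpha) for any input
        for _ in range(30):
            rr = float(rng.uniform(0, 0.02))
            n_pat = int(rng.integers(1, 400))
            n_mat = int(rng.integers(1, 400))
            out = maternal_and_overall(rr, (rr, rr), n_pat, n_mat)
            expected = rr * (out["p_pat"] + out["p_mat"] * out["alpha_ratio"])
            assert out["rr_overall"] == pytest.approx(expected, rel=1e-12)

    def test_eighty_twenty_split_gives_alpha_four_and_factor_1_6(self):
        out = maternal_and_overall(0.0027, (0.0009, 0.0046), 80, 20)
        assert out["alpha_ratio"] == 4.0
        assert out["rr_overall"] == pytest.approx(1.6 * 0.0027)

    def test_zero_maternal_count_is_undefined(self):
        out = maternal_and_overall(0.0027, (0.0, 0.005), 80, 0)
        assert math.isnan(out["rr_mat"]) and "warning" in out


class TestAdjustedEvents:
    def test_declared_approximation(self):
        out = adjusted_events_per_child(7, 5, 428, 334)
        assert out["adjusted_rate"] == pytest.approx(7 / 5 * 428 / 334)
        assert out["adjusted_rate"] == pytest.approx(1.79, abs=0.005)

    def test_fully_assessed_is_unadjusted(self):
        out = adjusted_events_per_child(5, 5, 400, 400)
        assert out["adjusted_rate"] == 1.0

    def test_zero_events_upper_ci_only(self):
        out = adjusted_events_per_child(0, 5, 400, 300)
        assert out["adjusted_rate"] == 0.0
        assert out["ci"][0] == 0.0 and out["ci"][1] > 0


def fisher_point_probability_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    n, row1, col1 = a + b + c + d, a + b, a + c
    def prob(x):
        return (math.comb(col1, x) * math.comb(n - col1, row1 - x)
                / math.comb(n, row1))
    p_obs = prob(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-7))


class TestEnrichment:
    def test_printed_table(self):
        out = enrichment_summary(6, 62, 7, 244)
        assert out["p_value"] == pytest.approx(0.0289, abs=1e-4)
        assert out["rate_ratio"] == pytest.approx(3.4, abs=0.05)

    def test_no_signal(self):
        assert enrichment_summary(0, 10, 0, 10)["p_value"] == 1.0

    def test_extreme_table_enumeration(self):
        out = enrichment_summary(5, 5, 0, 5)
        assert out["p_value"] == pytest.approx(2 / math.comb(10, 5), rel=1e-9)

    def test_matches_full_enumeration(self, rng):
        for _ in range(25):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
            if (a + b) == 0 or (c + d) == 0:
                continue
            out = enrichment_summary(a, a + b, c, c + d)
            oracle = fisher_point_probability_oracle(a, b, c, d)
            assert out["p_value"] == pytest.approx(oracle, rel=1e-9)


class TestGroupComparisons:
    def test_all_positive_pairs_minimal_exact_p(self):
        blood = np.linspace(0.01, 0.07, 7)
        sperm = blood + 0.02
        out = group_comparisons(blood, sperm, [])
        assert out["wilcoxon_p"] == pytest.approx(2 / 2**7)
        assert out["median_difference"] == pytest.approx(0.02)

    def test_identical_vectors_give_p_one(self):
        v = np.array([0.01, 0.02, 0.03])
        out = group_comparisons(v, v, [])
        assert out["wilcoxon_p"] == 1.0 and "warning" in out

    def test_signed_rank_matches_sign_flip_enumeration(self, rng):
        # oracle: full 2^n enumeration of sign assignments on |differences|
        diffs = rng.uniform(0.005, 0.05, size=7) * rng.choice([-1, 1], 7)
        blood = rng.uniform(0.01, 0.1, size=7)
        sperm = blood + diffs
        out = group_comparisons(blood, sperm, [])
        absd = np.abs(diffs)
        ranks = stats.rankdata(absd)
        w_obs = ranks[diffs > 0].sum()
        n = len(diffs)
        stats_all = []
        for signs in itertools.product([0, 1], repeat=n):
            stats_all.append(sum(r for s, r in zip(signs, ranks) if s))
        stats_all = np.array(stats_all)
        mean_w = stats_all.mean()
        p_oracle = np.mean(np.abs(stats_all - mean_w)
                           >= abs(w_obs - mean_w) - 1e-12)
        assert out["wilcoxon_p"] == pytest.approx(p_oracle, rel=1e-9)

    def test_rank_sum_against_small_enumeration(self):
        # U test on {1,2} vs {3,4,5}: complete separation
        out = group_comparisons([], [], [])
        assert out == {} or "wilcoxon_p" not in out
        res = group_comparisons(np.array([0.1, 0.2]),
                                np.array([0.3, 0.4]),
                                np.array([0.01, 0.02, 0.03]))
        # all sperm-only below shared: two-sided exact p = 2 * 1/C(5,2)
        assert res["mannwhitney_p"] == pytest.approx(2 / math.comb(5, 2))


def test_recurrence_report_end_to_end(small_result):
    report = small_result.report
    assert report.rr_pat <= report.rr_pat_raw + 1e-15
    assert report.alpha_ratio > 0
    w = report.p_pat + report.p_mat * report.alpha_ratio
    assert report.rr_overall == pytest.approx(report.rr_pat * w, rel=1e-9)
    assert all(v >= 0 for v in (report.rr_pat, report.rr_mat,
                                report.rr_overall))
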