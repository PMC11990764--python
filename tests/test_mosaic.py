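"""Deep-count mosaic testing: exact rate test, test plan, calls, screens."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dnmosaic.config import Thresholds
from dnmosaic.mosaic import (call_mosaics, classify_postzygotic,
                             control_noise_median, detection_power,
                             enumerate_tests, pool_controls, rate_test,
                             rate_test_vectorized, screen_metrics,
                             simulate_null_batches, wgs_altread_screen)


class TestRateTest:
    def test_zero_observation_gives_p_one(self):
        assert rate_test(0, 5000, 3, 40000) == 1.0
        assert rate_test(0, 5000, 0, 40000) == 1.0

    def test_clear_mosaic_is_significant(self):
        # VAF 0.2% at 5000x against noise 0.005%: far below the
        # experiment-wide Bonferroni threshold
        assert rate_test(10, 5000, 2, 40000) < 7.8e-5

    def test_equals_conditional_tail_enumeration(self, rng):
        # oracle: brute-force upper tail of Binomial(k, n_t/(n_t+n_c))
        for _ in range(300):
            k = int(rng.integers(0, 51))
            alt_t = int(rng.integers(0, k + 1))
            n_t = int(rng.integers(100, 50_000))
            n_c = int(rng.integers(100, 100_000))
            q = n_t / (n_t + n_c)
            brute = sum(math.comb(k, j) * q**j * (1 - q) ** (k - j)
                        for j in range(alt_t, k + 1))
            assert rate_test(alt_t, n_t, k - alt_t, n_c) == pytest.approx(
                brute, abs=1e-12)

    def test_monotone_in_test_and_control_counts(self):
        ps = [rate_test(a, 5000, 5, 40000) for a in range(0, 30)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))
        ps = [rate_test(8, 5000, c, 40000) for c in range(0, 30)]
        assert all(p1 <= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_naive_poisson_degenerates_at_zero_control(self):
        # the plug-in tail calls any observation certain when controls are
        # clean; the conditional test stays finite -- the reason it is default
        assert rate_test(1, 5000, 0, 40000, naive_poisson=True) == 0.0
        assert rate_test(1, 5000, 0, 40000) > 0.01

    def test_contract_violations(self):
        with pytest.raises(ValueError):
            rate_test(-1, 100, 0, 100)
        with pytest.raises(ValueError):
            rate_test(1, 0, 0, 100)

    def test_null_p_values_are_valid(self, rng):
        # conservative exact test: P(p <= t) <= t (+ MC error) under the null
        n = 100_000
        alt_t = rng.binomial(8000, 2.2e-4, size=n)
        alt_c = rng.binomial(33000, 2.2e-4, size=n)
        p = rate_test_vectorized(alt_t, 8000, alt_c, 33000)
        for t in (0.05, 0.01, 7.8e-5):
            frac = np.mean(p <= t)
            assert frac <= t + 3 * math.sqrt(t * (1 - t) / n)


class TestPoolControls:
    def counts_frame(self, n_trios=5, alt=0, total=8000):
        rows = []
        for t in range(1, n_trios + 1):
            for tissue, member in (("child_blood", "child"),
                                   ("father_blood", "father"),
                                   ("mother_blood", "mother"),
                                   ("father_sperm", "father")):
                suffix = "sperm" if tissue == "father_sperm" else "blood"
                rows.append(("v1", f"trio{t}", f"trio{t}_{member}_{suffix}",
                             tissue, total - alt, alt, 0, "primary"))
        return pd.DataFrame(rows, columns=[
            "variant_key", "trio", "sample", "tissue", "ref_count",
            "alt_count", "other_count", "replicate"])

    def test_sums_over_other_families(self):
        pool = pool_controls(self.counts_frame(), "trio1")
        # 4 other families x 4 samples x 8000 reads
        assert pool.alt["v1"] == 0
        assert pool.total["v1"] == 128_000
        assert pool.n_samples["v1"] == 16

    def test_missing_position_excluded_and_counted(self):
        df = self.counts_frame()
        df.loc[(df.trio == "trio2") & (df.tissue == "father_sperm"),
               ["ref_count", "alt_count"]] = 0
        pool = pool_controls(df, "trio1")
        assert pool.n_samples["v1"] == 15
        assert pool.total["v1"] == 120_000

    def test_no_controls_is_fatal(self):
        df = self.counts_frame(n_trios=1)
        with pytest.raises(ValueError, match="control"):
            pool_controls(df, "trio1")

    def test_median_control_vaf_near_configured_noise(self, default_cohort):
        truth = default_cohort.truth
        median = control_noise_median(
            default_cohort.counts,
            dict(zip(truth.variant_key, truth.trio_id)))
        assert median == pytest.approx(2.2e-4, rel=0.5)


class TestEnumerateTests:
    def phased(self, n_pat, n_mat, n_unphased):
        origins = (["paternal"] * n_pat + ["maternal"] * n_mat
                   + ["unphased"] * n_unphased)
        return pd.DataFrame({
            "variant_key": [f"v{i}" for i in range(len(origins))],
            "trio_id": "trio1", "parent_of_origin": origins})

    def test_haplotype_coherent_counts(self):
        plan, n, thr = enumerate_tests(self.phased(244, 62, 28))
        assert n == 244 * 2 + 62 + 28 * 3 == 634
        assert thr == 0.05 / 634

    def test_threshold_at_printed_test_count(self):
        _, _, thr = enumerate_tests(self.phased(0, 637, 0))
        assert thr == pytest.approx(7.8e-5, rel=0.01)

    def test_empty_plan_gives_nan_threshold(self):
        plan, n, thr = enumerate_tests(self.phased(0, 0, 0))
        assert n == 0 and math.isnan(thr)

    def test_tissues_per_origin(self):
        plan, _, _ = enumerate_tests(self.phased(1, 1, 1))
        by_variant = plan.groupby("variant_key").tissue.apply(set)
        assert by_variant["v0"] == {"father_blood", "father_sperm"}
        assert by_variant["v1"] == {"mother_blood"}
        assert by_variant["v2"] == {"father_blood", "father_sperm",
                                    "mother_blood"}


class TestCallMosaics:
    def test_injected_mosaics_confirmed_on_clear_margins(self, small_cohort,
                                                         small_result):
        truth = small_cohort.truth
        calls = small_result.mosaic_calls
        for row in truth.itertuples():
            for tissue, vaf in (("father_blood", row.vaf_father_blood),
                                ("mother_blood", row.vaf_mother_blood),
                                ("father_sperm", row.vaf_father_sperm)):
                sub = calls[(calls.variant_key == row.variant_key)
                            & (calls.tissue == tissue)]
                if vaf >= 0.02 and len(sub):
                    assert sub.confirmed.all(), (row.variant_key, tissue)

    def test_null_variants_not_called(self, small_cohort, small_result):
        # one-off variants have no parental signal: confirmed calls on them
        # are bounded by the experiment-wide error rate
        truth = small_cohort.truth
        null_keys = set(truth[truth.origin_category == "one_off"].variant_key)
        calls = small_result.mosaic_calls
        false_conf = calls[calls.variant_key.isin(null_keys) & calls.confirmed]
        assert len(false_conf) == 0

    def test_paternal_blood_mosaic_also_significant_in_sperm(
            self, small_cohort, small_result):
        # sperm VAF >= blood VAF by construction for shared mosaics
        truth = small_cohort.truth
        shared = truth[(truth.origin_category == "pre_pgc_blood")
                       & (truth.parent_of_origin == "paternal")]
        calls = small_result.mosaic_calls
        for key in shared.variant_key:
            blood = calls[(calls.variant_key == key)
                          & (calls.tissue == "father_blood")]
            sperm = calls[(calls.variant_key == key)
                          & (calls.tissue == "father_sperm")]
            if len(blood) and blood.significant.all():
                assert sperm.significant.all()

    def test_n_tests_matches_executed_plan(self, small_result):
        calls = small_result.mosaic_calls
        assert (calls.n_tests_total == len(calls)).all()
        assert calls.threshold.iloc[0] == pytest.approx(
            0.05 / len(calls))

    def test_significant_implies_p_below_threshold(self, small_result):
        calls = small_result.mosaic_calls
        sig = calls[calls.significant]
        assert (sig.p_primary < sig.threshold).all()
        conf = calls[calls.confirmed]
        assert conf.significant.all()
        assert (conf.p_confirmation < conf.threshold).all()


class TestPostzygotic:
    thr = Thresholds()

    def test_both_metrics_low_is_postzygotic(self):
        eligible, pz = classify_postzygotic(0.30, 0.50, 20, "SNV", "maternal",
                                            thresholds=self.thr)
        assert eligible and pz

    def test_constitutional_metrics_not_postzygotic(self):
        eligible, pz = classify_postzygotic(0.48, 0.95, 20, "SNV", "paternal",
                                            thresholds=self.thr)
        assert eligible and not pz

    @pytest.mark.parametrize("kwargs", [
        {"origin_hap_depth": 3},               # below 4x haplotype depth
        {"variant_type": "indel"},
        {"parent_of_origin": "unphased"},
        {"repeat_flag": True},
    ])
    def test_ineligibility_reasons(self, kwargs):
        base = dict(child_smmip_vaf=0.30, hap_specific_vaf=0.50,
                    origin_hap_depth=20, variant_type="SNV",
                    parent_of_origin="maternal", repeat_flag=False)
        base.update(kwargs)
        eligible, pz = classify_postzygotic(thresholds=self.thr, **base)
        assert not eligible and not pz

    def test_one_low_metric_is_not_enough(self):
        # only the deep-count VAF deviates: no call
        eligible, pz = classify_postzygotic(0.40, 0.97, 20, "SNV", "paternal",
                                            thresholds=self.thr)
        assert eligible and not pz


class TestWgsScreen:
    def pileup(self, alts):
        return pd.DataFrame({
            "variant_key": [f"v{i}" for i in range(len(alts))],
            "trio_id": "trio1", "sample": "father1",
            "alt_count": alts, "depth": 40})

    def test_confusion_counts(self):
        # 13 true mosaics, 10 with alt reads, plus 5 false positives
        alts = [2] * 10 + [0] * 3 + [1] * 5
        truth = {f"v{i}" for i in range(13)}
        out = wgs_altread_screen(self.pileup(alts), truth, min_alt=1)
        assert out["recall"] == pytest.approx(10 / 13)
        assert out["precision"] == pytest.approx(10 / 15)

    def test_no_candidates_undefined_precision(self):
        out = wgs_altread_screen(self.pileup([0, 0, 0]), {"v0"}, min_alt=1)
        assert out["n_candidates"] == 0
        assert out["recall"] == 0
        assert math.isnan(out["precision"])

    def test_recall_monotone_in_threshold(self, rng):
        alts = rng.poisson(0.8, size=40).tolist()
        truth = {f"v{i}" for i in range(0, 40, 3)}
        r1 = wgs_altread_screen(self.pileup(alts), truth, min_alt=1)["recall"]
        r2 = wgs_altread_screen(self.pileup(alts), truth, min_alt=2)["recall"]
        assert r2 <= r1

    def test_printed_confusion_metrics(self):
        out = screen_metrics(10, 13, 15)
        assert out["recall"] * 100 == pytest.approx(76.9, abs=0.05)
        assert out["precision"] * 100 == pytest.approx(66.7, abs=0.05)


class TestCalibration:
    def test_family_wise_error_controlled(self, rng):
        # scaled-down version of the full null experiment for speed
        fwe = simulate_null_batches(200, 637, 2.2e-4, 8000, 33000, 0.05, rng)
        assert fwe <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / 200)

    def test_power_at_half_percent_vaf(self):
        power = detection_power(0.005, 5000, 2.2e-4, 33000, 7.8e-5)
        assert power**2 >= 0.99   # confirmed = significant in both replicates
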