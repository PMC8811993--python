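"""Unit tests for the statistical toolkit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from faleak import (
    backward_stepwise_logistic,
    binormal_auc,
    chi_square_2x2,
    delong_paired_test,
    delong_variance_and_ci,
    empirical_auc,
    icc_agreement,
    mean_simulated_auc,
    two_sample_t,
)

from .oracles import bootstrap_auc_se, pair_count_auc


class TestEmpiricalAuc:
    def test_perfect_separation(self):
        assert empirical_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert empirical_auc([5, 5, 5, 5], [0, 0, 1, 1]) == 0.5

    def test_matches_pair_counting(self, rng):
        for _ in range(50):
            n = rng.integers(6, 30)
            scores = np.round(rng.normal(0, 1, n), 1)  # induce some ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert empirical_auc(scores, labels) == pytest.approx(
                pair_count_auc(scores, labels))

    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=30))
    def test_complement_identity(self, scores):
        labels = ([0, 1] * 15)[: len(scores)]
        a = empirical_auc(scores, labels)
        b = empirical_auc([-s for s in scores], labels)
        assert a + b == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            empirical_auc([1, 2, 3], [1, 1, 1])


class TestDelongVariance:
    def test_perfect_separation_zero_se(self):
        auc, se, ci = delong_variance_and_ci([1, 2, 10, 20], [0, 0, 1, 1])
        assert auc == 1.0 and se == 0.0

    def test_ci_contains_point_estimate(self, rng):
        for _ in range(20):
            scores = rng.normal(0, 1, 40)
            labels = np.r_[np.zeros(20), np.ones(20)]
            auc, se, (lo, hi) = delong_variance_and_ci(scores, labels)
            assert lo <= auc <= hi
            assert 0.0 <= lo and hi <= 1.0

    def test_se_close_to_bootstrap(self, rng):
        neg = rng.normal(0, 1, 25)
        pos = rng.normal(1, 1, 25)
        scores = np.r_[neg, pos]
        labels = np.r_[np.zeros(25), np.ones(25)]
        _, se, _ = delong_variance_and_ci(scores, labels)
        boot = bootstrap_auc_se(scores, labels, n_boot=2000, seed=1)
        assert se == pytest.approx(boot, rel=0.15)

    def test_degenerate_class_rejected(self):
        with pytest.raises(ValueError):
            delong_variance_and_ci([1, 2, 3], [0, 1, 1])


class TestDelongPaired:
    def test_identical_predictors(self):
        scores = [0.1, 0.9, 0.4, 0.8, 0.2, 0.7]
        labels = [0, 1, 0, 1, 0, 1]
        z, p = delong_paired_test(scores, scores, labels)
        assert z == 0.0 and p == 1.0

    def test_sign_symmetry(self, rng):
        labels = np.r_[np.zeros(15), np.ones(15)]
        a = rng.normal(labels, 1.0)
        b = rng.normal(0.6 * labels, 1.0)
        z1, p1 = delong_paired_test(a, b, labels)
        z2, p2 = delong_paired_test(b, a, labels)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_type_i_error_calibration(self, rng):
        # iid predictors: the paired p-value must be ~uniform
        pvals = []
        for _ in range(2000):
            labels = np.r_[np.zeros(20), np.ones(20)]
            a = rng.normal(labels, 1.0)
            b = rng.normal(labels, 1.0)
            pvals.append(delong_paired_test(a, b, labels)[1])
        d, p_ks = sps.kstest(pvals, "uniform")
        assert p_ks > 0.001

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            delong_paired_test([1, 2], [1, 2, 3], [0, 1, 1])


class TestBinormalAuc:
    def test_equal_distributions(self):
        assert binormal_auc(0, 1, 0, 1) == 0.5

    def test_reported_auc_values_from_group_moments(self):
        # perifoveal and CRT group moments imply the published AUCs
        assert binormal_auc(14.9, 8.9, 32.7, 15.0) == pytest.approx(0.846, abs=0.01)
        assert binormal_auc(451, 157, 544, 183) == pytest.approx(0.653, abs=0.01)

    def test_strictly_increasing_in_positive_mean(self):
        aucs = [binormal_auc(0, 1, mu, 1) for mu in (0.0, 0.5, 1.0, 2.0)]
        assert all(a < b for a, b in zip(aucs, aucs[1:]))

    def test_matches_empirical_auc_on_large_sample(self, rng):
        mu_n, sd_n, mu_p, sd_p = 10.0, 3.0, 14.0, 5.0
        n = 20_000
        scores = np.r_[rng.normal(mu_n, sd_n, n), rng.normal(mu_p, sd_p, n)]
        labels = np.r_[np.zeros(n), np.ones(n)]
        emp = empirical_auc(scores, labels)
        mc_se = np.sqrt(0.25 / n)  # generous bound on the AUC's MC error
        assert abs(emp - binormal_auc(mu_n, sd_n, mu_p, sd_p)) < 3 * mc_se

    def test_mean_simulated_auc_matches_closed_form(self):
        sim = mean_simulated_auc(14.9, 8.9, 47, 32.7, 15.0, 42,
                                 n_replicates=4000, seed=5)
        assert sim == pytest.approx(binormal_auc(14.9, 8.9, 32.7, 15.0), abs=0.01)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            binormal_auc(0, 0, 1, 1)


class TestIcc:
    def test_identical_vectors(self):
        x = [1.0, 5.0, 9.0, 2.0]
        assert icc_agreement(x, x) == pytest.approx(1.0)

    def test_dominant_noise_gives_low_icc(self, rng):
        a = rng.normal(0, 1, 1000)
        b = a + rng.normal(0, 3, 1000)
        assert icc_agreement(a, b) < 0.2

    def test_shift_of_one_grader_lowers_agreement(self, rng):
        truth = rng.normal(20, 10, 500)
        a = truth + rng.normal(0, 2, 500)
        b = truth + rng.normal(0, 2, 500)
        base = icc_agreement(a, b)
        assert icc_agreement(a, b + 8.0) < base

    def test_matches_pingouin_two_way_random_single(self, rng):
        pg = pytest.importorskip("pingouin")
        a = rng.normal(30, 10, 40)
        b = a + rng.normal(1.0, 4, 40)
        mine = icc_agreement(a, b)
        long = pd.DataFrame({
            "subject": np.r_[np.arange(40), np.arange(40)],
            "rater": ["r1"] * 40 + ["r2"] * 40,
            "score": np.r_[a, b],
        })
        ref = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score")
        # ICC(A,1): two-way, absolute agreement, single measure
        icc2 = ref.loc[ref["Type"].isin(["ICC(A,1)", "ICC2"]), "ICC"].iloc[0]
        assert mine == pytest.approx(float(icc2), abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            icc_agreement([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])


class TestTwoSampleT:
    def test_identical_groups(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_textbook_value(self):
        t, _ = two_sample_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=0.001)

    def test_injection_count_contrast_is_decisive(self, rng):
        # group moments of the yearly injection counts: p < .001 virtually always
        x = rng.normal(2.4, 1.2, (1000, 47))
        y = rng.normal(5.9, 1.6, (1000, 42))
        _, p = sps.ttest_ind(x, y, axis=1)
        assert (p < 0.001).mean() >= 0.99

    def test_welch_flag(self, rng):
        # unequal group sizes + unequal variances: pooled and Welch disagree
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.5, 4, 40)
        t_pooled, p_pooled = two_sample_t(x, y)
        t_welch, p_welch = two_sample_t(x, y, welch=True)
        assert t_pooled != t_welch and p_pooled != p_welch


class TestChiSquare:
    def test_reported_sex_distribution(self):
        _, p = chi_square_2x2([[30, 17], [26, 16]])
        assert p == pytest.approx(0.851, abs=0.005)

    def test_reported_laterality_distribution(self):
        _, p = chi_square_2x2([[26, 21], [23, 19]])
        assert p == pytest.approx(0.958, abs=0.005)

    def test_balanced_table(self):
        chi2, p = chi_square_2x2([[10, 10], [10, 10]])
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2([[0, 0], [5, 5]])


class TestBackwardStepwise:
    def _simulate(self, rng, n=89, beta=np.log(1.144), with_noise=True):
        x = rng.normal(23.3, 15.1, n)
        eta = -3.25 + beta * x
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        X = pd.DataFrame({"perifoveal_mgv": x})
        if with_noise:
            X["noise"] = rng.normal(0, 1, n)
        return X, y.astype(int)

    def test_strong_covariate_retained(self, rng):
        X, y = self._simulate(rng, n=500, with_noise=False)
        trace = backward_stepwise_logistic(X, y)
        assert "perifoveal_mgv" in trace.final
        assert trace.removed == []

    def test_noise_covariate_removed(self, rng):
        removed = 0
        for _ in range(50):
            X, y = self._simulate(rng)
            trace = backward_stepwise_logistic(X, y)
            if all(v != "noise" for v in trace.final):
                removed += 1
        assert removed >= 40

    def test_odds_ratio_ci_covers_truth(self, rng):
        covered = 0
        reps = 100
        for _ in range(reps):
            X, y = self._simulate(rng, with_noise=False)
            trace = backward_stepwise_logistic(X, y)
            if "perifoveal_mgv" not in trace.final:
                continue
            lo, hi = trace.final["perifoveal_mgv"]["or_ci95"]
            covered += lo <= 1.144 <= hi
        assert covered >= 0.85 * reps

    def test_separation_flagged_not_fatal(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0, 10.0, 11.0, 12.0]})
        y = np.array([0, 0, 0, 1, 1, 1])
        trace = backward_stepwise_logistic(X, y)
        assert trace.separation_flag

    def test_missing_values_rejected(self):
        X = pd.DataFrame({"x": [1.0, np.nan, 3.0]})
        with pytest.raises(ValueError, match="missing"):
            backward_stepwise_logistic(X, [0, 1, 1])
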