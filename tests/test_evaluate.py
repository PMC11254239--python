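import numpy as np
import pandas as pd
import pytest
from scipy import stats

from habitomics.evaluate import (
    classification_metrics,
    decision_curve,
    delong_test,
    hosmer_lemeshow,
    km_logrank,
    roc_auc_ci,
    youden_cutoff,
)
from reference import naive_auc_and_delong_var


class TestAuc:
    def test_perfect_separation(self):
        y = np.repeat([0, 1], 10)
        s = np.concatenate([np.linspace(0, 0.4, 10), np.linspace(0.6, 1, 10)])
        auc, lo, hi = roc_auc_ci(s, y)
        assert auc == 1.0
        assert hi == 1.0

    def test_null_scores_near_half(self, rng):
        y = rng.integers(0, 2, 4000)
        s = rng.random(4000)
        auc, lo, hi = roc_auc_ci(s, y)
        assert auc == pytest.approx(0.5, abs=0.03)
        assert lo <= 0.5 <= hi

    def test_matches_brute_force_pair_count_and_variance(self, rng):
        """10-observation toy set with ties: AUC equals the exhaustive
        concordant-pair count and the DeLong variance matches the
        direct placement-value computation."""
        y = np.array([1, 1, 1, 0, 0, 0, 0, 1, 0, 0])
        s = np.array([0.9, 0.8, 0.8, 0.8, 0.3, 0.2, 0.6, 0.5, 0.5, 0.1])
        auc, lo, hi = roc_auc_ci(s, y)
        ref_auc, ref_var = naive_auc_and_delong_var(s, y)
        assert auc == pytest.approx(ref_auc, abs=1e-12)
        half = stats.norm.ppf(0.975) * np.sqrt(ref_var)
        assert hi - auc == pytest.approx(min(half, 1 - auc), abs=1e-10)

    def test_monotone_transform_invariance(self, rng):
        y = rng.integers(0, 2, 200)
        s = rng.normal(size=200)
        a1, _, _ = roc_auc_ci(s, y)
        a2, _, _ = roc_auc_ci(np.exp(3 * s), y)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc_ci(np.array([0.1, 0.2]), np.array([1, 1]))


class TestDelong:
    def test_self_comparison_p_one(self, rng):
        y = rng.integers(0, 2, 50)
        s = rng.random(50)
        with pytest.warns(UserWarning):
            assert delong_test(s, s, y) == 1.0

    def test_monotone_transform_p_one(self, rng):
        y = rng.integers(0, 2, 60)
        s = rng.random(60)
        with pytest.warns(UserWarning):
            p = delong_test(s, 1 / (1 + np.exp(-5 * s)), y)
        assert p == 1.0

    def test_against_permutation_oracle(self):
        """n=30: the DeLong p agrees with a stratified permutation test
        of the AUC difference (swapping the two models' scores per
        subject) within Monte-Carlo error."""
        rng = np.random.default_rng(7)
        n = 30
        y = np.array([1] * 10 + [0] * 20)
        s_a = y * 0.8 + rng.normal(0, 0.6, n)
        s_b = y * 0.3 + rng.normal(0, 0.6, n)
        p_delong = delong_test(s_a, s_b, y)

        def auc(s):
            return roc_auc_ci(s, y)[0]

        obs = abs(auc(s_a) - auc(s_b))
        n_perm = 10_000
        count = 0
        for _ in range(n_perm):
            flip = rng.random(n) < 0.5
            pa = np.where(flip, s_b, s_a)
            pb = np.where(flip, s_a, s_b)
            if abs(auc(pa) - auc(pb)) >= obs - 1e-12:
                count += 1
        p_perm = count / n_perm
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert p_delong == pytest.approx(p_perm, abs=max(4 * se, 0.02))

    def test_detects_clear_difference(self, rng):
        y = np.repeat([0, 1], 100)
        good = y + rng.normal(0, 0.3, 200)
        bad = rng.normal(0, 1, 200)
        assert delong_test(good, bad, y) < 0.001


class TestClassificationMetrics:
    def test_perfect_predictions(self):
        y = np.repeat([0, 1], 20)
        s = y.astype(float)
        m = classification_metrics(s, y, cutoff=0.5, n_boot=100)
        assert (m["value"] == 1.0).all()

    def test_all_negative_closed_form(self):
        y = np.repeat([1, 0], [10, 90])
        s = np.zeros(100)
        with pytest.warns(UserWarning):
            m = classification_metrics(s, y, cutoff=0.5, n_boot=50).set_index("metric")
        assert m.loc["sensitivity", "value"] == 0.0
        assert m.loc["specificity", "value"] == 1.0
        assert m.loc["accuracy", "value"] == pytest.approx(0.9)
        assert m.loc["f1", "value"] == 0.0

    def test_hand_built_confusion_table(self):
        """TP=9, FN=2, FP=13, TN=69 at cutoff 0.5."""
        y = np.array([1] * 9 + [1] * 2 + [0] * 13 + [0] * 69)
        s = np.array([0.9] * 9 + [0.1] * 2 + [0.9] * 13 + [0.1] * 69)
        m = classification_metrics(s, y, cutoff=0.5, n_boot=50).set_index("metric")
        assert m.loc["sensitivity", "value"] == pytest.approx(9 / 11)
        assert m.loc["specificity", "value"] == pytest.approx(69 / 82)
        assert m.loc["f1", "value"] == pytest.approx(2 * 9 / (2 * 9 + 13 + 2))
        assert (m["ci_low"] <= m["value"]).all() and (m["value"] <= m["ci_high"]).all()


class TestDecisionCurve:
    def test_treat_all_limit_is_prevalence(self, rng):
        y = rng.integers(0, 2, 500)
        s = rng.random(500)
        dc = decision_curve(s, y, thresholds=[0.001])
        assert dc["treat_all"].iloc[0] == pytest.approx(y.mean(), abs=0.01)

    def test_no_positive_predictions_zero_benefit(self, rng):
        y = rng.integers(0, 2, 100)
        dc = decision_curve(np.zeros(100), y, thresholds=np.arange(0.1, 0.6, 0.1))
        assert (dc["net_benefit"] == 0.0).all()

    def test_hand_arithmetic_toy_cohort(self):
        """n=20, 8 positives; at t=0.2 the model flags 10 patients of
        whom 6 are true positives: NB = 6/20 - (4/20)(0.2/0.8) = 0.25."""
        y = np.array([1] * 6 + [0] * 4 + [1] * 2 + [0] * 8)
        s = np.array([0.9] * 10 + [0.1] * 10)
        dc = decision_curve(s, y, thresholds=[0.2])
        assert dc["net_benefit"].iloc[0] == pytest.approx(6 / 20 - (4 / 20) * 0.25)
        assert dc["treat_none"].iloc[0] == 0.0

    def test_net_benefit_bounded_by_prevalence(self, rng):
        y = rng.integers(0, 2, 300)
        s = rng.random(300)
        dc = decision_curve(s, y)
        assert (dc["net_benefit"] <= y.mean() + 1e-12).all()

    def test_invalid_threshold_rejected(self, rng):
        with pytest.raises(ValueError):
            decision_curve(rng.random(10), rng.integers(0, 2, 10), thresholds=[1.0])


class TestHosmerLemeshow:
    def test_perfectly_calibrated_construction(self):
        """Probabilities exactly equal to group event rates: chi2 = 0."""
        probs = np.repeat([0.2, 0.5, 0.8], 10)
        y = np.concatenate(
            [[1, 1, 0, 0, 0, 0, 0, 0, 0, 0],
             [1, 1, 1, 1, 1, 0, 0, 0, 0, 0],
             [1, 1, 1, 1, 1, 1, 1, 1, 0, 0]]
        )
        chi2, p, df = hosmer_lemeshow(probs, y, n_groups=3)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_two_group_hand_example(self):
        """Two groups of 10: expected 2 and 6 events, observed 4 and 5.
        chi2 = (4-2)^2/(2*0.8) + (5-6)^2/(6*0.4) = 2.5 + 0.41666..."""
        probs = np.repeat([0.2, 0.6], 10)
        y = np.concatenate([[1] * 4 + [0] * 6, [1] * 5 + [0] * 5])
        chi2, p, df = hosmer_lemeshow(probs, y, n_groups=2)
        expect = (4 - 2) ** 2 / (2 * (1 - 0.2)) + (5 - 6) ** 2 / (6 * (1 - 0.6))
        assert chi2 == pytest.approx(expect, abs=1e-10)


class TestYouden:
    def test_perfect_separation_index_one(self):
        y = np.repeat([0, 1], 10)
        s = np.concatenate([np.zeros(10), np.ones(10)])
        cut, j = youden_cutoff(s, y)
        assert j == pytest.approx(1.0)
        assert 0 < cut < 1

    def test_null_scores_index_small(self, rng):
        y = rng.integers(0, 2, 1000)
        s = rng.random(1000)
        _, j = youden_cutoff(s, y)
        assert j < 0.15

    def test_matches_exhaustive_scan(self, rng):
        from habitomics.evaluate import _metrics_at

        y = rng.integers(0, 2, 12)
        if y.sum() in (0, 12):
            y[0] = 1 - y[0]
        s = rng.random(12)
        cut, j = youden_cutoff(s, y)
        best = max(
            _metrics_at(s, y, c)["sensitivity"] + _metrics_at(s, y, c)["specificity"] - 1
            for c in np.concatenate([s - 1e-9, s + 1e-9])
        )
        assert j == pytest.approx(best, abs=1e-12)


class TestKmLogrank:
    def test_identical_groups_p_near_one(self, rng):
        t = rng.exponential(10, 400)
        e = np.ones(400, dtype=int)
        g = np.repeat([0, 1], 200)
        km = km_logrank(t, e, g)
        assert km["logrank_p"] > 0.05

    def test_textbook_product_limit_steps(self):
        """Classic 6-subject example (times 6,6,6,7,10,13; the 7 and 10
        censored): S(6) = 1/2, and S stays 1/2 until the event at 13.

        By hand: at t=6, 3 events among 6 at risk -> S = 1 - 3/6 = 0.5;
        censoring at 7 and 10 removes subjects without events;
        at t=13 one event with one at risk -> S = 0.
        """
        from lifelines import KaplanMeierFitter

        kmf = KaplanMeierFitter().fit([6, 6, 6, 7, 10, 13], [1, 1, 1, 0, 0, 1])
        assert float(kmf.predict(6.0)) == pytest.approx(0.5)
        assert float(kmf.predict(12.0)) == pytest.approx(0.5)
        assert float(kmf.predict(13.0)) == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survivor(self, rng):
        t = rng.exponential(12, 100).round(2) + 0.01
        e = np.ones(100, int)
        g = np.repeat([0, 1], 50)
        km = km_logrank(t, e, g, horizon=10.0)
        for lab in (0, 1):
            sel = g == lab
            emp = (t[sel] > 10.0).mean()
            assert km["groups"][lab]["survival_at_horizon"] == pytest.approx(emp, abs=1e-9)

    def test_hazard_ratio_power(self):
        """Exponential groups at hazard ratio 4, n=200: the log-rank
        test rejects in >= 95% of seeds."""
        from habitomics.experiments import logrank_power

        assert logrank_power(n_reps=40, n=200, hazard_ratio=4.0, seed=0) >= 0.95

    def test_km_nonincreasing(self, rng):
        t = rng.exponential(10, 80) + 0.1
        e = rng.integers(0, 2, 80)
        g = np.repeat([0, 1], 40)
        if e[:40].sum() == 0 or e[40:].sum() == 0:
            e[0] = e[40] = 1
        km = km_logrank(t, e, g)
        for lab in (0, 1):
            curve = km["groups"][lab]["curve"][:, 1]
            assert (np.diff(curve) <= 1e-12).all()
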