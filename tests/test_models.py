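import numpy as np
import pandas as pd
import pytest

from habitomics.models import (
    MODEL_NAMES,
    SMALL_GRID,
    aggregate_subregion_score,
    build_model_suite,
    fit_elasticnet_logistic,
    score_patients,
)


def _frame(arr, prefix="f"):
    return pd.DataFrame(arr, columns=[f"{prefix}{i}" for i in range(arr.shape[1])])


class TestElasticNetFit:
    def test_separable_data_perfect_training_auc(self, rng):
        X = _frame(np.vstack([rng.normal(-3, 0.3, (30, 2)), rng.normal(3, 0.3, (30, 2))]))
        y = np.repeat([0, 1], 30)
        model = fit_elasticnet_logistic(X, y, grid=SMALL_GRID, n_folds=4, seed=0)
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(y, model.score(X)) == 1.0

    def test_ridge_matches_independent_optimizer(self, rng):
        """l1_ratio=0 at fixed C: coefficients match direct numerical
        minimization of the class-weighted ridge-penalized negative
        log-likelihood (scipy optimizer, independent code path)."""
        from scipy.optimize import minimize

        n = 120
        X = rng.normal(size=(n, 3))
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.5 * X[:, 0] - X[:, 1])))).astype(int)
        C = 0.5
        grid = {"l1_ratio": (0.0,), "C": (C,), "max_iter": (20000,), "tol": (1e-8,)}
        model = fit_elasticnet_logistic(_frame(X), y, grid=grid, n_folds=3, seed=0)
        Z = (X - X.mean(0)) / X.std(0)
        w1 = n / (2 * y.sum())
        w0 = n / (2 * (n - y.sum()))
        sw = np.where(y == 1, w1, w0)

        def nll(params):
            b0, b = params[0], params[1:]
            eta = b0 + Z @ b
            ll = sw * (y * eta - np.log1p(np.exp(eta)))
            return -ll.sum() + 0.5 / C * (b @ b)

        res = minimize(nll, np.zeros(4), method="BFGS", options={"gtol": 1e-10})
        assert np.allclose(model.estimator.coef_.ravel(), res.x[1:], atol=1e-4)
        assert model.estimator.intercept_[0] == pytest.approx(res.x[0], abs=1e-4)

    def test_balanced_weights_fix_imbalanced_positive_rate(self, rng):
        """10:1 imbalance with no signal: the balanced fit predicts
        positive for roughly half the samples at the 0.5 cutoff,
        unlike an unweighted fit (which predicts almost none)."""
        from sklearn.linear_model import LogisticRegression

        n = 1100
        X = rng.normal(size=(n, 3))
        y = np.array([1] * 100 + [0] * 1000)
        grid = {"l1_ratio": (0.0,), "C": (1.0,), "max_iter": (2000,), "tol": (1e-6,)}
        model = fit_elasticnet_logistic(_frame(X), y, grid=grid, n_folds=3, seed=0)
        rate_bal = (model.score(_frame(X)) >= 0.5).mean()
        unw = LogisticRegression(C=1.0).fit(X, y)
        rate_unw = (unw.predict_proba(X)[:, 1] >= 0.5).mean()
        assert abs(rate_bal - 0.5) < 0.15
        assert rate_unw < 0.05

    def test_deterministic_refit(self, rng):
        X = _frame(rng.normal(size=(60, 4)))
        y = rng.integers(0, 2, 60)
        m1 = fit_elasticnet_logistic(X, y, grid=SMALL_GRID, n_folds=3, seed=5)
        m2 = fit_elasticnet_logistic(X, y, grid=SMALL_GRID, n_folds=3, seed=5)
        assert np.array_equal(m1.estimator.coef_, m2.estimator.coef_)
        assert m1.best_params == m2.best_params

    def test_tie_break_prefers_stronger_regularization(self, rng):
        """On separable data many grid points reach CV AUC 1; the
        winner is the smallest C among them."""
        X = _frame(np.vstack([rng.normal(-5, 0.2, (40, 2)), rng.normal(5, 0.2, (40, 2))]))
        y = np.repeat([0, 1], 40)
        model = fit_elasticnet_logistic(X, y, grid=SMALL_GRID, n_folds=4, seed=0)
        t = model.cv_table
        best = t["cv_auc"].max()
        c_at_best = t.loc[t["cv_auc"] == best, "C"].min()
        assert model.best_params["C"] == c_at_best


class TestScoring:
    def test_all_zero_features_give_intercept_probability(self, rng):
        X = _frame(rng.normal(size=(80, 2)))
        y = rng.integers(0, 2, 80)
        grid = {"l1_ratio": (0.0,), "C": (1.0,), "max_iter": (2000,), "tol": (1e-6,)}
        model = fit_elasticnet_logistic(X, y, grid=grid, n_folds=3, seed=0)
        # rows at the training mean standardize to zero
        x0 = pd.DataFrame([X.mean()], columns=X.columns)
        p = model.score(x0)[0]
        b0 = model.estimator.intercept_[0]
        assert p == pytest.approx(1 / (1 + np.exp(-b0)), abs=1e-10)

    def test_scores_match_linear_algebra_oracle(self, rng):
        X = _frame(rng.normal(size=(100, 5)))
        y = rng.integers(0, 2, 100)
        grid = {"l1_ratio": (0.5,), "C": (1.0,), "max_iter": (5000,), "tol": (1e-8,)}
        model = fit_elasticnet_logistic(X, y, grid=grid, n_folds=3, seed=0)
        Xnew = _frame(rng.normal(size=(100, 5)))
        Z = (Xnew.to_numpy() - model.mean) / model.scale
        eta = Z @ model.estimator.coef_.ravel() + model.estimator.intercept_[0]
        assert np.allclose(score_patients(model, Xnew), 1 / (1 + np.exp(-eta)), atol=1e-10)

    def test_missing_column_named_in_error(self, rng):
        X = _frame(rng.normal(size=(40, 3)))
        y = rng.integers(0, 2, 40)
        grid = {"l1_ratio": (0.0,), "C": (1.0,), "max_iter": (1000,), "tol": (1e-4,)}
        model = fit_elasticnet_logistic(X, y, grid=grid, n_folds=3, seed=0)
        with pytest.raises(KeyError, match="f2"):
            model.score(X[["f0", "f1"]])


class TestAggregate:
    def test_printed_formula_mean(self):
        assert aggregate_subregion_score([0.2, 0.4, 0.6]) == pytest.approx(0.4)

    def test_single_region_identity(self):
        assert aggregate_subregion_score([0.73]) == 0.73

    def test_constant_scores_any_V(self):
        for v in (1, 3, 7):
            assert aggregate_subregion_score([0.31] * v) == pytest.approx(0.31)

    def test_permutation_invariant_and_bounded(self, rng):
        s = list(rng.random(6))
        a = aggregate_subregion_score(s)
        b = aggregate_subregion_score(s[::-1])
        assert a == pytest.approx(b, abs=1e-14)
        assert min(s) <= a <= max(s)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            aggregate_subregion_score([])


def _toy_suite_inputs(rng, n=40):
    from habitomics.phantom import generate_clinical_cohort

    table = generate_clinical_cohort(n, 0.25, seed=11)
    y = table.set_index("patient_id")["msi"]
    # two subregions per patient; f0 informative for the subregion block
    sub_rows = []
    for pid in table["patient_id"]:
        for r in (1, 2):
            sub_rows.append(
                {
                    "patient_id": pid,
                    "region_id": r,
                    "s0": y.loc[pid] * 1.5 + rng.normal(0, 0.8),
                    "s1": rng.normal(),
                }
            )
    sub = pd.DataFrame(sub_rows)
    cl = pd.DataFrame(
        {
            "patient_id": table["patient_id"],
            "c0": y.loc[table["patient_id"]].to_numpy() * 1.0 + rng.normal(0, 1.0, n),
            "c1": rng.normal(size=n),
        }
    )
    return table, sub, cl


class TestModelSuite:
    def test_contains_five_named_models(self, rng):
        table, sub, cl = _toy_suite_inputs(rng)
        suite = build_model_suite(
            sub, cl, table, ["s0"], ["c0"], ["location[high]"],
            grid=SMALL_GRID, n_folds=3, seed=0,
        )
        assert set(suite.models) == set(MODEL_NAMES)
        assert set(MODEL_NAMES).issubset(suite.patient_scores.columns)

    def test_patient_score_is_mean_of_region_scores(self, rng):
        table, sub, cl = _toy_suite_inputs(rng)
        suite = build_model_suite(
            sub, cl, table, ["s0"], ["c0"], ["location[high]"],
            grid=SMALL_GRID, n_folds=3, seed=0,
        )
        region_scores = suite.models["subregion"].score(sub[["s0"]])
        per_pat = (
            pd.DataFrame({"pid": sub["patient_id"], "s": region_scores})
            .groupby("pid")["s"].mean()
        )
        got = suite.patient_scores.set_index("patient_id")["subregion"]
        assert np.allclose(got.loc[per_pat.index], per_pat, atol=1e-12)

    def test_leakage_guard_rejects_unknown_patients(self, rng):
        table, sub, cl = _toy_suite_inputs(rng)
        sub.loc[0, "patient_id"] = "GHOST"
        with pytest.raises(ValueError, match="GHOST"):
            build_model_suite(
                sub, cl, table, ["s0"], ["c0"], ["location[high]"],
                grid=SMALL_GRID, n_folds=3, seed=0,
            )

    def test_empty_clinical_selection_degrades_gracefully(self, rng):
        table, sub, cl = _toy_suite_inputs(rng)
        with pytest.warns(UserWarning, match="intercept-only"):
            suite = build_model_suite(
                sub, cl, table, ["s0"], ["c0"], [],
                grid=SMALL_GRID, n_folds=3, seed=0,
            )
        assert len(np.unique(suite.patient_scores["clinical"])) == 1

    def test_training_rows_only_reach_fits(self, rng):
        """Perturbing every external-test row leaves the fitted
        coefficients bit-identical (train/test separation)."""
        table, sub, cl = _toy_suite_inputs(rng)
        suite1 = build_model_suite(
            sub, cl, table, ["s0"], ["c0"], ["location[high]"],
            grid=SMALL_GRID, n_folds=3, seed=0,
        )
        test_ids = set(table.loc[table["cohort"] == "external_test", "patient_id"])
        sub2 = sub.copy()
        sub2.loc[sub2["patient_id"].isin(test_ids), ["s0", "s1"]] += 100.0
        cl2 = cl.copy()
        cl2.loc[cl2["patient_id"].isin(test_ids), ["c0", "c1"]] -= 50.0
        suite2 = build_model_suite(
            sub2, cl2, table, ["s0"], ["c0"], ["location[high]"],
            grid=SMALL_GRID, n_folds=3, seed=0,
        )
        for name in MODEL_NAMES:
            e1, e2 = suite1.models[name].estimator, suite2.models[name].estimator
            if e1 is None:
                continue
            assert np.array_equal(e1.coef_, e2.coef_), name
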