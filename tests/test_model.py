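"""Logistic fitting, AUC, cost-sensitive thresholds and bootstrapped CV."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import norm

import radkinetics as rk
from radkinetics.model import FinalModel, PerformanceReport, SweepResult

from oracles import brute_threshold_cost


class TestFitLogistic:
    def test_null_data_gives_prevalence_intercept(self, rng):
        n = 5000
        X = pd.DataFrame({"x": rng.normal(size=n)})
        y = (rng.uniform(size=n) < 0.3).astype(int)
        spec = rk.fit_logistic(X, y)
        assert spec.coefficients["x"] == pytest.approx(0.0, abs=0.1)
        assert spec.intercept == pytest.approx(logit(y.mean()), abs=0.1)

    def test_parameter_recovery(self, rng):
        n = 10_000
        beta = np.array([-0.5, 1.0, -0.7])
        X = rng.normal(size=(n, 2))
        p = expit(beta[0] + X @ beta[1:])
        y = (rng.uniform(size=n) < p).astype(int)
        spec = rk.fit_logistic(pd.DataFrame(X, columns=["a", "b"]), y)
        assert spec.intercept == pytest.approx(beta[0], abs=0.1)
        assert spec.coefficients["a"] == pytest.approx(beta[1], abs=0.1)
        assert spec.coefficients["b"] == pytest.approx(beta[2], abs=0.1)

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n = 300
        X = rng.normal(size=(n, 2))
        y = (rng.uniform(size=n) < expit(0.3 + X[:, 0] - 0.5 * X[:, 1])).astype(int)
        spec = rk.fit_logistic(pd.DataFrame(X, columns=["a", "b"]), y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(
            [spec.intercept, spec.coefficients["a"], spec.coefficients["b"]],
            ref.params, atol=1e-5,
        )

    def test_duplicated_rows_equal_weighted_fit(self, rng):
        n = 80
        X = rng.normal(size=(n, 1))
        y = (rng.uniform(size=n) < expit(X[:, 0])).astype(int)
        df = pd.DataFrame(X, columns=["a"])
        s1 = rk.fit_logistic(pd.concat([df, df], ignore_index=True),
                             np.concatenate([y, y]))
        s2 = rk.fit_logistic(df, y)
        assert s1.coefficients["a"] == pytest.approx(s2.coefficients["a"], abs=1e-6)
        assert s1.intercept == pytest.approx(s2.intercept, abs=1e-6)

    def test_perfect_separation_warns_and_stays_finite(self):
        X = pd.DataFrame({"a": [-2.0, -1.0, 1.0, 2.0]})
        y = np.array([0, 0, 1, 1])
        with pytest.warns(UserWarning, match="separation"):
            spec = rk.fit_logistic(X, y)
        assert np.isfinite(spec.coefficients["a"])

    def test_single_class_rejected(self):
        with pytest.raises(rk.InvalidInputError):
            rk.fit_logistic(pd.DataFrame({"a": [1.0, 2.0]}), np.array([1, 1]))

    def test_model_type_invariants(self):
        with pytest.raises(rk.ConfigurationError):
            rk.ModelSpec("dose_only", ["a"], 0.0, {"a": 1.0})
        with pytest.raises(rk.ConfigurationError):
            rk.ModelSpec("radiomics_plus_dose", ["a"], 0.0, {"a": 1.0})


class TestAUC:
    def test_perfect_separation(self):
        assert rk.auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_hand_counted_pairs(self):
        assert rk.auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_ties_counted_half(self):
        assert rk.auc([0.5, 0.5], [0, 1]) == pytest.approx(0.5)

    def test_invariant_under_monotone_transform(self, rng):
        s = rng.normal(size=50)
        y = rng.integers(0, 2, size=50)
        y[0], y[1] = 0, 1
        assert rk.auc(s, y) == pytest.approx(rk.auc(np.exp(s), y), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        s = rng.normal(size=200)
        y = rng.integers(0, 2, size=200)
        y[0], y[1] = 0, 1
        assert rk.auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(rk.InvalidInputError):
            rk.auc([0.1, 0.9], [1, 1])


class TestCostSensitive:
    def test_separable_zero_cost(self):
        t, sens, spec, acc = rk.cost_sensitive_metrics(
            np.array([0.2, 0.4, 0.6, 0.8]), np.array([0, 0, 1, 1]), 3.0)
        assert (sens, spec, acc) == (1.0, 1.0, 1.0)

    def test_hand_worked_example(self):
        t, sens, spec, acc = rk.cost_sensitive_metrics(
            np.array([0.2, 0.3, 0.6, 0.7]), np.array([0, 1, 0, 1]), 3.0)
        assert 0.2 < t < 0.3
        assert sens == 1.0 and spec == 0.5 and acc == pytest.approx(0.75)

    def test_extreme_cost_ratio_forces_full_sensitivity(self, rng):
        probs = rng.uniform(size=40)
        y = rng.integers(0, 2, size=40)
        y[0], y[1] = 0, 1
        t, sens, _, _ = rk.cost_sensitive_metrics(probs, y, 1e9)
        assert sens == 1.0
        assert t <= probs[y == 1].min()

    def test_threshold_cost_is_global_minimum(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 30))
            probs = np.round(rng.uniform(size=n), 2)
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            t = rk.choose_threshold(probs, y, 3.0)
            pred = probs >= t
            cost = 3.0 * np.sum((y == 1) & ~pred) + np.sum((y == 0) & pred)
            assert cost == brute_threshold_cost(list(probs), list(y), 3.0)


class TestEvaluate:
    def _noise_data(self, rng, n=120, k=2):
        X = pd.DataFrame(rng.normal(size=(n, k)),
                         columns=[f"c{j}" for j in range(k)])
        y = np.r_[np.ones(n // 2, dtype=int), np.zeros(n - n // 2, dtype=int)]
        return X, y

    def test_bit_exact_reproducibility(self, rng):
        X, y = self._noise_data(rng)
        kw = dict(predictors_by_type={"radiomics_only": ["c0"]},
                  config=rk.EvalConfig(n_bootstrap=3, seed=5))
        r1 = rk.evaluate(X, y, **kw)
        r2 = rk.evaluate(X, y, **kw)
        assert r1.summary.equals(r2.summary)
        for k_ in r1.raw["radiomics_only"]:
            np.testing.assert_array_equal(
                r1.raw["radiomics_only"][k_], r2.raw["radiomics_only"][k_])

    def test_stratified_folds_balanced_within_one_patient(self, rng):
        from radkinetics.model import _stratified_allocations
        y = (rng.uniform(size=100) < 0.37).astype(int)
        cfg = rk.EvalConfig(n_bootstrap=10, seed=1)
        overall = y.mean()
        for splits in _stratified_allocations(y, cfg):
            seen = []
            for _, te in splits:
                k = len(te)
                assert abs(y[te].sum() - overall * k) <= 1.0
                seen.extend(te)
            assert sorted(seen) == list(range(100))

    def test_null_predictors_auc_near_half(self, rng):
        X, y = self._noise_data(rng, n=200)
        rep = rk.evaluate(X, y, {"radiomics_only": ["c0", "c1"]},
                          rk.EvalConfig(n_bootstrap=40, seed=2))
        assert 0.45 <= rep.median("radiomics_only", "auc", "test") <= 0.55

    def test_binormal_closed_form(self):
        """Single predictor with class shift d: test AUC approaches
        Phi(d / sqrt(2))."""
        r = np.random.default_rng(8)
        n, d = 500, 1.0
        y = (r.uniform(size=n) < 0.4).astype(int)
        X = pd.DataFrame({"c0": r.normal(size=n) + d * y})
        rep = rk.evaluate(X, y, {"radiomics_only": ["c0"]},
                          rk.EvalConfig(n_bootstrap=30, seed=3))
        assert rep.median("radiomics_only", "auc", "test") == pytest.approx(
            norm.cdf(d / np.sqrt(2)), abs=0.03
        )

    def test_train_auc_not_below_test_auc(self, small_trajectory_cohort):
        coh = small_trajectory_cohort
        m = rk.standardize(rk.build_slope_matrix(
            coh.to_feature_table(), weeks=[15], doses=coh.doses))
        y = coh.outcomes["6m"].reindex(m.data.index).to_numpy()
        rep = rk.evaluate(
            m.data, y,
            {"radiomics_plus_dose": ["feature_000_fx1_15", "mean_dose"]},
            rk.EvalConfig(n_bootstrap=40, seed=4))
        assert rep.median("radiomics_plus_dose", "auc", "train") >= \
            rep.median("radiomics_plus_dose", "auc", "test")

    def test_minority_class_smaller_than_k_rejected(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=10)})
        y = np.r_[np.ones(2, dtype=int), np.zeros(8, dtype=int)]
        with pytest.raises(rk.InvalidInputError):
            rk.evaluate(X, y, {"radiomics_only": ["a"]}, rk.EvalConfig(k_folds=3))


@pytest.fixture(scope="module")
def sweep(small_trajectory_cohort):
    coh = small_trajectory_cohort
    return rk.weekly_sweep(
        coh.to_feature_table(), coh.outcomes, coh.doses,
        sel_config=rk.SelectionConfig(n_repeats=25, seed=2),
        eval_config=rk.EvalConfig(n_bootstrap=25, seed=3),
    )


class TestWeeklySweepAndFinalModel:

    def test_grid_covers_requested_weeks_only(self, sweep):
        assert sorted(x for _, x in sweep.reports) == [5, 10, 15]

    def test_dose_only_constant_across_weeks(self, sweep):
        meds = [sweep.reports[("6m", x)].median("dose_only", "auc", "test")
                for x in (5, 10, 15)]
        assert max(meds) - min(meds) < 1e-12

    def test_final_model_maximises_test_auc_within_three_weeks(
            self, sweep, small_trajectory_cohort):
        coh = small_trajectory_cohort
        finals = rk.select_final_model(sweep, coh.outcomes, "6m", max_week=15)
        for mt, fm in finals.items():
            best = max(
                (sweep.reports[("6m", x)].median(mt, "auc", "test"), -x)
                for x in (5, 10, 15)
            )
            assert fm.auc_test_median == pytest.approx(best[0])

    def test_week_constraint_binds(self):
        """A late-week AUC peak outside the eligibility window is ignored
        and ties break to the earliest week."""
        def fake_report(week, auc_by_type):
            rows = [
                {"model_type": mt, "endpoint": "6m", "week": week,
                 "metric": "auc", "split": "test", "median": a,
                 "ci_lo": a, "ci_hi": a}
                for mt, a in auc_by_type.items()
            ]
            return PerformanceReport(summary=pd.DataFrame(rows), raw={},
                                     pooled_test={}, endpoint="6m", week=week)

        aucs = {5: 0.70, 10: 0.74, 15: 0.72, 20: 0.80}
        reports, tallies, matrices = {}, {}, {}
        df = pd.DataFrame({"f_fx1_5": [0.1, -0.2, 0.3, 0.0],
                           "mean_dose": [1.0, -1.0, 0.5, -0.5]},
                          index=pd.Index([f"P{i}" for i in range(4)],
                                         name="patient_id"))
        for w, a in aucs.items():
            reports[("6m", w)] = fake_report(w, {mt: a for mt in
                                                 ("dose_only", "radiomics_only",
                                                  "radiomics_plus_dose")})
            tallies[("6m", w)] = rk.SelectionTally({frozenset(["f_fx1_5"]): 1}, 1)
            matrices[("6m", w)] = rk.SlopeMatrix(df)
        sweep = SweepResult(reports=reports, tallies=tallies, matrices=matrices)
        outcomes = pd.DataFrame({"6m": [1, 0, 1, 0]}, index=df.index)
        finals = rk.select_final_model(sweep, outcomes, "6m", max_week=15)
        assert all(fm.week == 10 for fm in finals.values())
        # flat sequence -> earliest week
        for w in aucs:
            reports[("6m", w)] = fake_report(w, {mt: 0.7 for mt in
                                                 ("dose_only", "radiomics_only",
                                                  "radiomics_plus_dose")})
        finals = rk.select_final_model(
            SweepResult(reports=reports, tallies=tallies, matrices=matrices),
            outcomes, "6m", max_week=15)
        assert all(fm.week == 5 for fm in finals.values())

    def test_small_endpoint_skipped(self, small_trajectory_cohort):
        coh = small_trajectory_cohort
        outcomes = coh.outcomes.iloc[:5]
        sweep = rk.weekly_sweep(coh.to_feature_table().head(400), outcomes,
                                coh.doses,
                                sel_config=rk.SelectionConfig(n_repeats=2, seed=0),
                                eval_config=rk.EvalConfig(n_bootstrap=2, seed=0))
        assert sweep.reports == {}
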