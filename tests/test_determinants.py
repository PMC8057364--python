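import numpy as np
import pandas as pd
import pytest

from catex import determinants as det


def _sigmoid(x):
    return 1 / (1 + np.exp(-x))


def make_logit_data(rng, n=800, coefs=(0.8, -0.5), intercept=-0.2,
                    binary_col=True):
    X = pd.DataFrame({"x1": rng.standard_normal(n)})
    if binary_col:
        X["d1"] = (rng.random(n) < 0.4).astype(float)
    else:
        X["x2"] = rng.standard_normal(n)
    eta = intercept + coefs[0] * X.iloc[:, 0] + coefs[1] * X.iloc[:, 1]
    y = (rng.random(n) < _sigmoid(eta)).astype(int)
    return det.DesignMatrix(pd.Series(y), X)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


class TestFitLogit:
    def test_intercept_only_closed_form(self, rng):
        y = pd.Series([1] * 60 + [0] * 40)
        dm = det.DesignMatrix(y, pd.DataFrame(index=y.index))
        fit = det.fit_logit(dm)
        assert fit.params["const"] == pytest.approx(np.log(0.6 / 0.4),
                                                    abs=1e-6)
        assert fit.converged

    def test_recovers_true_coefficients(self, rng):
        dm = make_logit_data(rng, n=5000, coefs=(0.8, -0.5))
        fit = det.fit_logit(dm)
        for name, true in zip(dm.covariates.columns, (0.8, -0.5)):
            assert abs(fit.params[name] - true) < 3 * fit.bse[name]
        assert 0 <= fit.pseudo_r2 <= 1
        assert fit.lr_chi2 > 0 and fit.lr_df == 2
        # CI brackets the coefficient
        assert (fit.ci95["lo"] <= fit.params).all()
        assert (fit.params <= fit.ci95["hi"]).all()

    def test_null_covariate_ci_covers_zero_at_nominal_rate(self, rng):
        hits = 0
        reps = 60
        for _ in range(reps):
            X = pd.DataFrame({"x": rng.standard_normal(400)})
            y = (rng.random(400) < 0.5).astype(int)
            fit = det.fit_logit(det.DesignMatrix(pd.Series(y), X))
            hits += fit.ci95.loc["x", "lo"] <= 0 <= fit.ci95.loc["x", "hi"]
        assert hits / reps > 0.85

    def test_perfect_separation_names_covariate(self):
        X = pd.DataFrame({"good": np.r_[np.zeros(20), np.ones(20)]})
        y = pd.Series(np.r_[np.zeros(20), np.ones(20)].astype(int))
        with pytest.raises(det.SeparationError, match="good"):
            det.fit_logit(det.DesignMatrix(y, X))

    def test_constant_response_rejected(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        with pytest.raises(ValueError):
            det.fit_logit(det.DesignMatrix(pd.Series([1] * 10), X))

    def test_gradient_small_at_optimum(self, rng):
        dm = make_logit_data(rng, n=2000)
        fit = det.fit_logit(dm)
        score = fit.sm_result.model.score(fit.sm_result.params)
        assert np.max(np.abs(score)) < 1e-5 * dm.n

    def test_pseudo_r2_invariant_to_covariate_rescaling(self, rng):
        dm = make_logit_data(rng, n=1500)
        r2 = det.fit_logit(dm).pseudo_r2
        X2 = dm.covariates.copy()
        X2["x1"] = X2["x1"] * 1000 + 7
        r2b = det.fit_logit(det.DesignMatrix(dm.response, X2)).pseudo_r2
        assert r2b == pytest.approx(r2, abs=1e-8)


class TestMarginalEffects:
    def test_ame_matches_finite_difference(self, rng):
        dm = make_logit_data(rng, n=1500)
        fit = det.marginal_effects(det.fit_logit(dm), dm)
        params = fit.params
        X = dm.covariates
        h = 1e-5

        def mean_p(Xmod):
            eta = params["const"] + Xmod.to_numpy() @ params[X.columns].to_numpy()
            return _sigmoid(eta).mean()

        # continuous: central finite difference
        Xp, Xm = X.copy(), X.copy()
        Xp["x1"] += h
        Xm["x1"] -= h
        fd = (mean_p(Xp) - mean_p(Xm)) / (2 * h)
        assert fit.marginal_effects["x1"] == pytest.approx(fd, abs=1e-6)
        # binary: counterfactual contrast
        X1, X0 = X.copy(), X.copy()
        X1["d1"], X0["d1"] = 1.0, 0.0
        assert fit.marginal_effects["d1"] == pytest.approx(
            mean_p(X1) - mean_p(X0), abs=1e-10)

    def test_zero_coefficient_gives_zero_ame(self, rng):
        dm = make_logit_data(rng, n=1000)
        fit = det.fit_logit(dm)
        forced = fit.sm_result.params.copy()
        forced["x1"] = 0.0  # a covariate with no effect
        fit.sm_result._results.params = forced.to_numpy()
        fit = det.marginal_effects(fit, dm)
        assert fit.marginal_effects["x1"] == 0.0

    def test_refuses_non_converged_fit(self, rng):
        dm = make_logit_data(rng, n=500)
        fit = det.fit_logit(dm)
        fit.converged = False
        with pytest.raises(RuntimeError):
            det.marginal_effects(fit, dm)


class TestFitLpm:
    def test_closed_form_on_hand_design(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0, 4.0]})
        y = pd.Series([0, 0, 1, 1, 1])
        fit = det.fit_lpm(det.DesignMatrix(y, X))
        # normal equations solved independently
        A = np.c_[np.ones(5), X["x"]]
        beta = np.linalg.solve(A.T @ A, A.T @ y.to_numpy())
        assert fit.params["const"] == pytest.approx(beta[0])
        assert fit.params["x"] == pytest.approx(beta[1])

    def test_perfect_fit(self):
        x = np.r_[np.zeros(5), np.ones(5)]
        dm = det.DesignMatrix(pd.Series(x.astype(int)),
                              pd.DataFrame({"x": x}))
        fit = det.fit_lpm(dm)
        assert fit.params["x"] == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)
        resid = fit.sm_result.resid
        assert np.abs(resid).max() < 1e-10

    def test_residuals_orthogonal_to_design(self, rng):
        dm = make_logit_data(rng, n=600)
        fit = det.fit_lpm(dm)
        resid = fit.sm_result.resid
        X = np.c_[np.ones(dm.n), dm.covariates.to_numpy()]
        inner = X.T @ resid
        scale = np.abs(X).sum(axis=0) * np.abs(resid).max()
        assert (np.abs(inner) < 1e-8 * np.maximum(scale, 1)).all()

    def test_rank_deficient_design_raises(self, rng):
        x = rng.standard_normal(50)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        y = pd.Series((x > 0).astype(int))
        with pytest.raises(np.linalg.LinAlgError):
            det.fit_lpm(det.DesignMatrix(y, X))


class TestStepwise:
    def test_thresholds_of_one_return_full_model(self, rng):
        dm = make_logit_data(rng, n=400)
        sel, fit, log = det.stepwise_select(dm, model="ols", p_enter=1.0,
                                            p_remove=1.0)
        assert set(sel) == set(dm.covariates.columns)

    def test_vanishing_entry_threshold_returns_empty_model(self, rng):
        dm = make_logit_data(rng, n=400)
        sel, fit, log = det.stepwise_select(dm, model="ols", p_enter=1e-300,
                                            p_remove=1e-299)
        assert sel == []
        assert list(fit.params.index) == ["const"]

    def test_single_strong_covariate_selected(self, rng):
        n = 500
        X = pd.DataFrame({"x": rng.standard_normal(n)})
        y = (rng.random(n) < _sigmoid(1.5 * X["x"])).astype(int)
        sel, fit, log = det.stepwise_select(
            det.DesignMatrix(pd.Series(y), X), model="logit")
        assert sel == ["x"]
        assert log.iloc[0]["action"] == "enter"

    def test_inadmissible_thresholds_rejected(self, rng):
        dm = make_logit_data(rng, n=200)
        with pytest.raises(ValueError):
            det.stepwise_select(dm, p_enter=0.2, p_remove=0.1)

    def test_audit_log_records_every_step(self, rng):
        n = 1000
        X = pd.DataFrame(rng.standard_normal((n, 4)),
                         columns=list("abcd"))
        y = (rng.random(n) < _sigmoid(0.8 * X["a"] - 0.6 * X["c"])).astype(int)
        sel, fit, log = det.stepwise_select(
            det.DesignMatrix(pd.Series(y), X), model="logit")
        assert {"a", "c"} <= set(sel)
        assert (log["action"].isin(["enter", "remove"])).all()
        entered = log[log["action"] == "enter"]["covariate"]
        removed = log[log["action"] == "remove"]["covariate"]
        assert sorted(sel) == sorted(set(entered) - set(removed) | (
            set(removed) & set()) | (set(entered[entered.duplicated()])))


class TestCompareModels:
    def test_identical_inputs_give_zero_differences(self, rng):
        dm = make_logit_data(rng, n=800)
        fit = det.marginal_effects(det.fit_logit(dm), dm)
        lpm = det.fit_lpm(dm)
        comp = det.compare_models(fit, lpm)
        comp2 = det.compare_models(fit, lpm)
        pd.testing.assert_frame_equal(comp, comp2)
        assert (comp["abs_difference"] >= 0).all()

    def test_name_mismatch_is_alignment_error(self, rng):
        dm = make_logit_data(rng, n=300)
        fit = det.marginal_effects(det.fit_logit(dm), dm)
        other = det.DesignMatrix(dm.response,
                                 dm.covariates.rename(columns={"x1": "z"}))
        lpm = det.fit_lpm(other)
        with pytest.raises(ValueError, match="mismatch"):
            det.compare_models(fit, lpm)


class TestContingency:
    def test_independence_gives_zero(self):
        flags = [0] * 20 + [1] * 20
        group = (["a", "b"] * 20)
        chi2, df, p = det.contingency_chi2(flags, group)
        assert chi2 == pytest.approx(0.0)
        assert df == 1

    def test_hand_formula_2x2(self):
        # table [[30,10],[10,30]]: chi2 = N(ad-bc)^2 / (row/col margins)
        flags = [0] * 40 + [1] * 40
        group = ["g1"] * 30 + ["g2"] * 10 + ["g1"] * 10 + ["g2"] * 30
        chi2, df, p = det.contingency_chi2(flags, group)
        expected = 80 * (30 * 30 - 10 * 10) ** 2 / (40 * 40 * 40 * 40)
        assert chi2 == pytest.approx(expected)  # = 20.0
        assert df == 1 and p < 1e-4

    def test_balanced_2x3(self):
        flags = ([0, 1] * 30)
        group = ["a", "a", "b", "b", "c", "c"] * 10
        chi2, df, p = det.contingency_chi2(flags, group)
        assert chi2 == pytest.approx(0.0)
        assert df == 2

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            det.contingency_chi2([0, 1, 0], ["a", "a", "a"])
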