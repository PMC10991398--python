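"""Cumulative-link fitting, r2ML, VIF, robustness fits."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from squadperf.ordinal import (
    ModelSpec,
    RankDeficientDesign,
    coefficient_difference,
    fit_interaction,
    fit_logistic_topk,
    fit_ordinal,
    fit_quadratic,
    fit_stratified,
    null_loglikelihood,
    predicted_vs_observed,
    r2_ml,
    vif,
)
from squadperf.simulate import simulate_proportional_odds

rng = np.random.default_rng(77)


def _po_frame(n=300, beta=(-1.0, 0.5), n_levels=4, seed=0):
    """A data frame drawn from an exact proportional-odds model."""
    r = np.random.default_rng(seed)
    X = r.normal(size=(n, len(beta)))
    theta = np.linspace(-1.5, 1.5, n_levels - 1)
    y = simulate_proportional_odds(X, np.asarray(beta), theta, r)
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(len(beta))])
    df["final_rank"] = y
    return df, theta


class TestFitOrdinal:
    def test_thresholds_increasing_and_logl_above_null(self):
        df, _ = _po_frame(n=400, seed=1)
        fit = fit_ordinal(df, ModelSpec(terms=("x0", "x1")), compute_vif=False)
        assert fit.converged
        assert (np.diff(fit.thresholds) > 0).all()
        assert fit.logl >= fit.logl_null - 1e-6
        assert 0 <= fit.r2_ml < 1

    def test_intercept_only_equals_null(self):
        df, _ = _po_frame(n=200, seed=2)
        fit = fit_ordinal(df, ModelSpec(terms=()))
        assert fit.logl == pytest.approx(fit.logl_null)
        assert fit.r2_ml == pytest.approx(0.0)

    def test_negating_a_feature_negates_its_coefficient(self):
        df, _ = _po_frame(n=300, seed=3)
        f1 = fit_ordinal(df, ModelSpec(terms=("x0", "x1")), compute_vif=False)
        df2 = df.assign(x0=-df["x0"])
        f2 = fit_ordinal(df2, ModelSpec(terms=("x0", "x1")), compute_vif=False)
        assert f2.params["x0"] == pytest.approx(-f1.params["x0"], abs=1e-5)
        assert f2.params["x1"] == pytest.approx(f1.params["x1"], abs=1e-5)

    def test_matches_brute_force_likelihood_search(self):
        """Independent MLE: hand-written likelihood + multi-start
        Nelder-Mead agrees with the module to 1e-4 in logL."""
        df, _ = _po_frame(n=120, beta=(-0.8,), n_levels=3, seed=4)
        fit = fit_ordinal(df, ModelSpec(terms=("x0",)), compute_vif=False)

        y = df["final_rank"].to_numpy()
        x = df["x0"].to_numpy()

        def negll(params):
            t1, dt, b = params
            theta = np.array([t1, t1 + abs(dt) + 1e-9])
            cdf = 1 / (1 + np.exp(-(np.concatenate([[-np.inf], theta, [np.inf]])[None, :] - (x * b)[:, None])))
            p = np.diff(cdf, axis=1)[np.arange(len(y)), y - 1]
            return -np.sum(np.log(np.maximum(p, 1e-300)))

        best = np.inf
        for start in ([-1, 2, 0], [0, 1, -1], [1, 1, 1], [-0.5, 0.5, -0.5]):
            res = minimize(negll, start, method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
            best = min(best, res.fun)
        assert fit.logl == pytest.approx(-best, abs=1e-4)

    def test_rank_deficient_design_names_collinear_terms(self):
        df, _ = _po_frame(n=200, seed=5)
        df["x2"] = df["x0"] + df["x1"]
        with pytest.raises(RankDeficientDesign, match="collinear"):
            fit_ordinal(df, ModelSpec(terms=("x0", "x1", "x2")))

    def test_parameter_recovery_coverage(self):
        """Reduced Monte Carlo: each beta-hat lands in its own 95% CI for
        the true value at a conservative floor of the nominal rate."""
        beta = np.array([-1.2, 0.7])
        hits = np.zeros(2)
        R = 25
        for i in range(R):
            df, _ = _po_frame(n=400, beta=tuple(beta), n_levels=6, seed=100 + i)
            f = fit_ordinal(df, ModelSpec(terms=("x0", "x1")), compute_vif=False)
            for j, t in enumerate(("x0", "x1")):
                hits[j] += f.ci_low[t] <= beta[j] <= f.ci_high[t]
        assert (hits >= 0.8 * R).all(), hits


class TestR2ML:
    def test_closed_forms(self):
        assert r2_ml(-100.0, -100.0, 50) == pytest.approx(0.0)
        n = 80
        assert r2_ml(-200.0, -200.0 + n / 2, n) == pytest.approx(1 - np.exp(-1.0))

    def test_monotone_in_model_logl(self):
        vals = [r2_ml(-100.0, -100.0 + g, 40) for g in (0.0, 5.0, 10.0)]
        assert vals[0] < vals[1] < vals[2]

    def test_domain_error(self):
        with pytest.raises(ValueError):
            r2_ml(-1.0, -1.0, 0)


class TestVIF:
    def test_orthogonal_columns_are_one(self):
        n = 400
        X = pd.DataFrame({"a": np.tile([1.0, -1.0], n // 2),
                          "b": np.repeat([1.0, -1.0], n // 2)})
        assert np.allclose(vif(X), 1.0, atol=1e-10)

    def test_duplicated_column_is_infinite(self):
        x = rng.normal(size=100)
        X = pd.DataFrame({"a": x, "b": x})
        assert np.isinf(vif(X)).all()

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        X = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        X["d"] = X["a"] * 0.8 + rng.normal(size=200) * 0.3
        ours = vif(X)
        import statsmodels.api as sm

        Xc = sm.add_constant(X.to_numpy())
        oracle = [variance_inflation_factor(Xc, i + 1) for i in range(4)]
        assert np.allclose(ours, oracle, atol=1e-8)


class TestRobustnessFits:
    def test_quadratic_centering_invariance(self):
        df, _ = _po_frame(n=300, seed=6)
        df["share_high"] = rng.uniform(size=300)
        df["final_rank"] = simulate_proportional_odds(
            df[["x0", "share_high"]].to_numpy(), [-1.0, 1.0],
            np.linspace(-1, 1, 4), np.random.default_rng(6),
        )
        spec = ModelSpec(terms=("x0", "share_high"))
        f1 = fit_quadratic(df, spec, which=("share_high",), compute_vif=False)
        df2 = df.assign(share_high=df["share_high"] + 10.0)
        f2 = fit_quadratic(df2, spec, which=("share_high",), compute_vif=False)
        # exact mathematically; numerically limited by the optimizer gtol
        assert f1.params["share_high_sq"] == pytest.approx(
            f2.params["share_high_sq"], abs=1e-3
        )

    def test_planted_quadratic_sign_recovered(self):
        r = np.random.default_rng(8)
        n = 1500
        s = r.uniform(size=n)
        X = np.column_stack([s, (s - s.mean()) ** 2])
        y = simulate_proportional_odds(X, [-2.0, 6.0], np.linspace(-1.5, 1, 9), r)
        df = pd.DataFrame({"share_high": s, "final_rank": y})
        f = fit_quadratic(df, ModelSpec(terms=("share_high",)),
                          which=("share_high",), compute_vif=False)
        assert f.params["share_high_sq"] > 0
        assert f.ci_low["share_high_sq"] > 0

    def test_interaction_requires_varying_moderator(self):
        df, _ = _po_frame(n=200, seed=9)
        df["share_high"] = rng.uniform(size=200)
        df["z_experience"] = 0.0
        with pytest.raises(RankDeficientDesign, match="z_experience"):
            fit_interaction(df, ModelSpec(terms=("x0", "share_high")))

    def test_logistic_topk_degenerate_outcome(self):
        df, _ = _po_frame(n=100, n_levels=4, seed=10)
        with pytest.raises(ValueError, match="degenerate"):
            fit_logistic_topk(df, ModelSpec(terms=("x0",)), k=10)

    def test_logistic_topk_null_logl_closed_form(self):
        df, _ = _po_frame(n=200, n_levels=4, seed=11)
        df["final_rank"] = np.tile([1, 2, 3, 4], 50)  # balanced: half <= 2
        fit = fit_logistic_topk(df, ModelSpec(terms=("x0",)), k=2)
        assert fit.logl_null == pytest.approx(200 * np.log(0.5))

    def test_logistic_agrees_with_ordinal_on_dominant_term(self):
        df, _ = _po_frame(n=600, beta=(-2.0, 0.3), n_levels=8, seed=12)
        fo = fit_ordinal(df, ModelSpec(terms=("x0", "x1")), compute_vif=False)
        fl = fit_logistic_topk(df, ModelSpec(terms=("x0", "x1")), k=4)
        # top-k success is the complement of a high rank: signs flip
        assert np.sign(fl.params["x0"]) == -np.sign(fo.params["x0"])


class TestStratifiedFits:
    def _stratified_frame(self, n=900, seed=13):
        r = np.random.default_rng(seed)
        df, _ = _po_frame(n=n, seed=seed)
        df["stratum"] = r.choice(["LOW", "MEDIUM", "HIGH"], size=n)
        return df

    def test_fits_are_local_to_their_stratum(self):
        df = self._stratified_frame()
        spec = ModelSpec(terms=("x0", "x1"))
        fits = fit_stratified(df, spec, min_rows=100, compute_vif=False)
        # permuting the other strata's rows leaves a stratum's fit unchanged
        scr = df.copy()
        mask = scr["stratum"] != "LOW"
        scr.loc[mask, "final_rank"] = (
            scr.loc[mask, "final_rank"].sample(frac=1, random_state=1).to_numpy()
        )
        refit = fit_ordinal(
            scr, ModelSpec(terms=("x0", "x1"), stratum_filter="LOW"), compute_vif=False
        )
        assert np.allclose(refit.params, fits["LOW"].params, atol=1e-6)

    def test_undersized_stratum_raises_with_counts(self):
        df = self._stratified_frame(n=120)
        with pytest.raises(ValueError, match="undersized"):
            fit_stratified(df, ModelSpec(terms=("x0",)), min_rows=200)


class TestCoefficientDifference:
    def test_printed_low_experience_gap_is_16_positions(self):
        table = {"low_interdependence": 4.842, "high_interdependence": -11.427}
        assert coefficient_difference(
            table, "low_interdependence", "high_interdependence"
        ) == pytest.approx(16.269)
        assert coefficient_difference(
            table, "low_interdependence", "high_interdependence", round_to_int=True
        ) == 16

    def test_printed_high_experience_gap_is_13_positions(self):
        table = {"low_interdependence": -0.774, "high_interdependence": -13.655}
        assert coefficient_difference(
            table, "low_interdependence", "high_interdependence", round_to_int=True
        ) == 13

    def test_identity_and_missing_term(self):
        assert coefficient_difference({"a": 2.0}, "a", "a") == 0.0
        with pytest.raises(KeyError):
            coefficient_difference({"a": 1.0}, "a", "b")


class TestPredictedVsObserved:
    def test_intercept_only_expected_is_marginal_mean(self):
        df, _ = _po_frame(n=240, n_levels=5, seed=14)
        fit = fit_ordinal(df, ModelSpec(terms=()))
        pvo = predicted_vs_observed(fit, df)
        assert np.allclose(pvo["expected"], df["final_rank"].mean(), atol=1e-9)

    def test_expected_ranks_within_level_range(self):
        df, _ = _po_frame(n=300, n_levels=6, seed=15)
        fit = fit_ordinal(df, ModelSpec(terms=("x0", "x1")), compute_vif=False)
        pvo = predicted_vs_observed(fit, df)
        assert (pvo["expected"] >= 1).all() and (pvo["expected"] <= 6).all()

    def test_strong_separation_tracks_observed(self):
        r = np.random.default_rng(16)
        n = 600
        x = r.normal(size=n)
        y = simulate_proportional_odds(x[:, None], [6.0], np.quantile(6 * x, [0.33, 0.66]), r)
        df = pd.DataFrame({"x0": x, "final_rank": y})
        fit = fit_ordinal(df, ModelSpec(terms=("x0",)), compute_vif=False)
        pvo = predicted_vs_observed(fit, df)
        corr = np.corrcoef(pvo["observed"], pvo["expected"])[0, 1]
        assert corr > 0.8


def test_null_loglikelihood_matches_counts():
    y = [1, 1, 2, 3, 3, 3]
    expect = 2 * np.log(2 / 6) + 1 * np.log(1 / 6) + 3 * np.log(3 / 6)
    assert null_loglikelihood(y) == pytest.approx(expect)
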