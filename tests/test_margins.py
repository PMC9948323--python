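"""Marginal standardization, delta/bootstrap CIs, interaction test, strata."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from rainmob import (
    DGPSpec,
    SplineSpec,
    build_design,
    fit_spline_logit,
    interaction_test,
    marginal_curve,
    marginal_probability,
    marginal_rr,
    run_stratified,
    true_marginal_rr,
)
from rainmob.experiments import simulate_panel, _fit
from rainmob.model import ModelFit
from rainmob.synthetic import ushape


def manual_fit(df, params, include_interaction=False):
    """A ModelFit with hand-set coefficients over a real design."""
    spec = SplineSpec((0.1, 0.5, 0.9))
    X, info = build_design(df, spec, include_interaction=include_interaction,
                           covariates=("married",) if include_interaction else (),
                           include_country=False, include_month=False)
    beta = pd.Series(0.0, index=X.columns)
    for k, v in params.items():
        beta[k] = v
    zeros = pd.DataFrame(np.zeros((len(beta), len(beta))), index=beta.index, columns=beta.index)
    return ModelFit(params=beta, vcov=zeros, vcov_naive=zeros, loglik=0.0,
                    n_obs=len(df), n_clusters=df["site_id"].nunique() if "site_id" in df else 1,
                    cr_type="CR1", n_iter=0, design_info=info)


@pytest.fixture(scope="module")
def fitted_ushape(ushape_panel):
    dgp, df = ushape_panel
    return dgp, df, _fit(df, knots=3)


class TestMarginalProbability:
    def test_intercept_only_is_expit(self):
        df = pd.DataFrame({"percentile": np.full(50, 0.3), "site_id": "S0"})
        fit = manual_fit(df, {"intercept": -1.7})
        assert marginal_probability(fit, df, 0.8) == pytest.approx(expit(-1.7), abs=1e-15)

    def test_strictly_inside_unit_interval(self, fitted_ushape):
        _, df, fit = fitted_ushape
        for p in (0.0, 0.15, 0.5, 0.85, 1.0):
            prob = marginal_probability(fit, df, p)
            assert 0.0 < prob < 1.0

    def test_matches_explicit_counterfactual_rows(self, fitted_ushape):
        """g-computation equals the oracle that rebuilds every row at p."""
        _, df, fit = fitted_ushape
        sub = df.groupby("country").head(125).reset_index(drop=True)
        for p in (0.15, 0.5, 0.85):
            got = marginal_probability(fit, sub, p)
            counterfactual = sub.assign(percentile=p)
            Xc, _ = build_design(counterfactual, fit.design_info.spline, covariates=(),
                                 include_country=True, include_month=False)
            Xc = Xc[fit.params.index]
            oracle = float(np.mean(expit(Xc.to_numpy() @ fit.params.to_numpy())))
            assert got == pytest.approx(oracle, abs=1e-12)


class TestMarginalRR:
    def test_identity_contrast(self, fitted_ushape):
        _, df, fit = fitted_ushape
        r = marginal_rr(fit, df, 0.5, 0.5)
        assert r.rr == 1.0 and r.se_log_rr == 0.0

    def test_null_exposure_coefficients_give_rr_one(self):
        df = pd.DataFrame({"percentile": np.random.default_rng(0).random(100), "site_id": "S0"})
        fit = manual_fit(df, {"intercept": -2.0})
        r = marginal_rr(fit, df, 0.15, 0.5)
        assert r.rr == pytest.approx(1.0, abs=1e-15)

    def test_ci_brackets_estimate(self, fitted_ushape):
        _, df, fit = fitted_ushape
        r = marginal_rr(fit, df, 0.15, 0.5)
        assert r.ci_low <= r.rr <= r.ci_high
        assert r.rr > 0 and r.se_log_rr > 0

    def test_recovery_against_closed_form(self):
        """No heterogeneity: estimated RR within 3 SEs of the expit ratio at n=100,000."""
        b0, gamma = float(logit(0.124)), 0.6
        dgp = DGPSpec(seed=31, n_countries=4, sites_per_country=250, respondents_per_site=100,
                      baseline_logit=b0, ushape_gamma=gamma, site_sd=0.0)
        df = simulate_panel(dgp)
        fit = _fit(df, knots=3)
        truth = expit(b0 + gamma * ushape(0.15)) / expit(b0 + gamma * ushape(0.5))
        r = marginal_rr(fit, df, 0.15, 0.5)
        assert abs(np.log(r.rr) - np.log(truth)) < 3 * r.se_log_rr

    def test_delta_and_cluster_bootstrap_agree(self):
        dgp = DGPSpec(seed=41, n_countries=2, sites_per_country=50, respondents_per_site=50,
                      ushape_gamma=0.6, site_sd=0.2)
        df = simulate_panel(dgp)
        fit = _fit(df, knots=3)
        delta = marginal_rr(fit, df, 0.15, 0.5, ci_method="delta")
        boot = marginal_rr(
            fit, df, 0.15, 0.5, ci_method="bootstrap", n_boot=200, boot_seed=7,
            refit=lambda d: _fit(d, knots=SplineSpec(fit.design_info.spline.knots)),
        )
        for a, b in ((delta.ci_low, boot.ci_low), (delta.ci_high, boot.ci_high)):
            assert abs(np.log(a) - np.log(b)) < 0.25 * max(abs(np.log(a)), abs(np.log(b)), 0.05)

    def test_degenerate_reference_raises(self):
        df = pd.DataFrame({"percentile": np.full(20, 0.5), "site_id": "S0"})
        fit = manual_fit(df, {"intercept": -800.0})
        with pytest.raises(ValueError, match="degenerate reference"):
            marginal_rr(fit, df, 0.15, 0.5)


class TestInteractionTest:
    def test_zero_interaction_coefficients(self):
        df = pd.DataFrame(
            {"percentile": np.random.default_rng(0).random(100),
             "married": [True, False] * 50, "site_id": "S0"}
        )
        fit = manual_fit(df, {"intercept": -2.0, "rcs1": 0.3}, include_interaction=True)
        fit.vcov.values[:] = np.eye(len(fit.params))
        t = interaction_test(fit)
        assert t.wald_stat == 0.0 and t.p_value == 1.0
        assert t.df == 2

    def test_missing_interaction_terms_raise(self, fitted_ushape):
        _, df, fit = fitted_ushape
        with pytest.raises(ValueError, match="no married x spline"):
            interaction_test(fit)

    def test_singular_subblock_raises(self):
        df = pd.DataFrame(
            {"percentile": np.random.default_rng(0).random(100),
             "married": [True, False] * 50, "site_id": "S0"}
        )
        fit = manual_fit(df, {"married_x_rcs1": 0.2}, include_interaction=True)
        with pytest.raises(ValueError, match="singular"):
            interaction_test(fit)  # vcov is all zeros

    def test_power_under_strong_effect_modification(self):
        """delta doubling the exposure effect for married -> frequent rejection."""
        from rainmob.experiments import interaction_power_study

        dgp = DGPSpec(seed=55, n_countries=4, sites_per_country=150, respondents_per_site=100,
                      ushape_gamma=0.5, interaction_delta=0.5, site_sd=0.2)
        res = interaction_power_study(dgp, n_reps=10)
        assert res["reject"].mean() > 0.9


class TestMarginalCurve:
    def test_flat_for_null_exposure_fit(self):
        df = pd.DataFrame({"percentile": np.random.default_rng(0).random(200), "site_id": "S0"})
        fit = manual_fit(df, {"intercept": -2.0})
        curve = marginal_curve(fit, df, np.linspace(0, 1, 21))
        probs = curve["marginal_probability"].to_numpy()
        assert np.max(np.abs(probs - probs[0])) < 1e-10

    def test_ushape_minimum_interior(self, fitted_ushape):
        _, df, fit = fitted_ushape
        curve = marginal_curve(fit, df, np.linspace(0, 1, 41))
        p_min = curve.loc[curve["marginal_probability"].idxmin(), "percentile"]
        assert 0.2 < p_min < 0.8

    def test_empty_grid_raises(self, fitted_ushape):
        _, df, fit = fitted_ushape
        with pytest.raises(ValueError, match="empty"):
            marginal_curve(fit, df, [])


class TestRunStratified:
    @staticmethod
    def _fits():
        base = lambda d: _fit(d, knots=3)
        inter = lambda d: _fit(d, knots=3, include_interaction=True)
        return base, inter

    def test_shape_matches_stratified_table(self):
        dgp = DGPSpec(seed=61, n_countries=2, sites_per_country=40, respondents_per_site=60,
                      ushape_gamma=0.5, site_sd=0.2, women_frac=0.5)
        df = simulate_panel(dgp)
        base, inter = self._fits()
        results, tests, skipped = run_stratified(df, base, inter)
        strata = [r.stratum for r in results]
        # 2 gender-level x 2 contrasts + 2x2 marital strata x 2 contrasts
        assert strata.count("women") == 2 and strata.count("men") == 2
        for s in ("women:married", "women:unmarried", "men:married", "men:unmarried"):
            assert strata.count(s) == 2
        assert set(tests) == {"women", "men"}
        assert skipped == []

    def test_null_dgp_rrs_near_one(self):
        dgp = DGPSpec(seed=62, n_countries=4, sites_per_country=250, respondents_per_site=100,
                      ushape_gamma=0.0, interaction_delta=0.0, site_sd=0.3, women_frac=0.5)
        df = simulate_panel(dgp)
        base, inter = self._fits()
        results, _, _ = run_stratified(df, base, inter)
        for r in results:
            assert 0.9 < r.rr < 1.1

    def test_effect_modification_ordering_women_only(self):
        """Married women get the extra drought effect; men do not."""
        women = DGPSpec(seed=63, n_countries=4, sites_per_country=150, respondents_per_site=100,
                        ushape_gamma=0.3, interaction_delta=0.6, site_sd=0.2, women_frac=1.0)
        men = DGPSpec(seed=64, n_countries=4, sites_per_country=150, respondents_per_site=100,
                      ushape_gamma=0.3, interaction_delta=0.0, site_sd=0.2, women_frac=0.0)
        dfw, dfm = simulate_panel(women), simulate_panel(men)
        dfm = dfm.assign(site_id="M" + dfm["site_id"].str[1:])
        df = pd.concat([dfw, dfm], ignore_index=True)
        base, inter = self._fits()
        results, tests, _ = run_stratified(df, base, inter)
        rr = {(r.stratum, r.p_cmp): r.rr for r in results}
        assert rr[("women:married", 0.15)] > rr[("women:unmarried", 0.15)]
        assert abs(np.log(rr[("men:married", 0.15)] / rr[("men:unmarried", 0.15)])) < np.log(
            rr[("women:married", 0.15)] / rr[("women:unmarried", 0.15)]
        )
        assert tests["women"].p_value < 0.05

    def test_degenerate_stratum_skipped_with_reason(self):
        dgp = DGPSpec(seed=65, n_countries=2, sites_per_country=20, respondents_per_site=30,
                      women_frac=1.0)
        df = simulate_panel(dgp)
        df.loc[df["married"], "mobile"] = 0  # married stratum has one class
        base, inter = self._fits()
        results, _, skipped = run_stratified(df, base, inter)
        assert any("married: single outcome class" in s for s in skipped)
        assert all(r.stratum != "women:married" for r in results)
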