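"""Marginal standardization (g-computation) over the fitted mobility model.

A marginal probability at exposure percentile p is the average, over every
respondent's observed covariates, of the model's predicted event
probability with the spline (and any married x spline interaction) columns
re-evaluated at p. Marginal risk ratios contrast two such percentiles —
drought (0.15) and heavy rain (0.85) against the median (0.50) by default.

Confidence intervals use the delta method on log RR with the
cluster-robust coefficient covariance:

    d/dbeta log RR = A_cmp / P_cmp - A_ref / P_ref,
    A = mean_i mu_i (1 - mu_i) x_i  (counterfactual rows),

with a seeded cluster bootstrap (resampling sites with replacement and
refitting) as the verification alternative. Effect modification by
marital status is a joint Wald chi-square test on the interaction
coefficients against the clustered covariance sub-block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm

from .model import ModelFit, design_at_percentile, fit_logistic

DROUGHT, MEDIAN, HEAVY = 0.15, 0.50, 0.85
DEFAULT_CONTRASTS = ((DROUGHT, MEDIAN), (HEAVY, MEDIAN))


@dataclass(frozen=True)
class MarginalResult:
    """A marginal-standardization risk-ratio contrast."""

    p_cmp: float
    p_ref: float
    prob_cmp: float
    prob_ref: float
    rr: float
    se_log_rr: float
    ci_low: float
    ci_high: float
    stratum: str = ""
    ci_method: str = "delta"

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "p_cmp": self.p_cmp,
            "p_ref": self.p_ref,
            "prob_cmp": self.prob_cmp,
            "prob_ref": self.prob_ref,
            "rr": self.rr,
            "se_log_rr": self.se_log_rr,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_method": self.ci_method,
        }


@dataclass(frozen=True)
class InteractionTest:
    """Joint Wald test of the married x spline interaction block."""

    wald_stat: float
    df: int
    p_value: float
    alpha: float = 0.05

    @property
    def effect_modification(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "wald_stat": self.wald_stat,
            "df": self.df,
            "p_value": self.p_value,
            "effect_modification": self.effect_modification,
        }


def _check_support(fit: ModelFit, data: pd.DataFrame, p: float, strict: bool) -> None:
    x = data["percentile"].to_numpy(float)
    if p < x.min() - 1e-12 or p > x.max() + 1e-12:
        msg = f"contrast percentile {p} outside the observed exposure support [{x.min():.3f}, {x.max():.3f}]"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=3)


def marginal_probability(fit: ModelFit, data: pd.DataFrame, p: float, strict: bool = False) -> float:
    """Mean predicted probability with everyone's exposure set to ``p``."""
    if fit.design_info is None:
        raise ValueError("fit carries no design metadata; refit via fit_spline_logit")
    _check_support(fit, data, p, strict)
    X = design_at_percentile(data, fit.design_info, p)
    return float(np.mean(expit(X.to_numpy(float) @ fit.params.to_numpy())))


def _prob_and_gradient(fit: ModelFit, data: pd.DataFrame, p: float) -> tuple[float, np.ndarray]:
    X = design_at_percentile(data, fit.design_info, p).to_numpy(float)
    mu = expit(X @ fit.params.to_numpy())
    return float(mu.mean()), (mu * (1.0 - mu)) @ X / len(mu)


def marginal_rr(
    fit: ModelFit,
    data: pd.DataFrame,
    p_cmp: float = DROUGHT,
    p_ref: float = MEDIAN,
    ci_method: str = "delta",
    level: float = 0.95,
    stratum: str = "",
    strict: bool = False,
    n_boot: int = 500,
    boot_seed: int = 0,
    cluster_col: str = "site_id",
    refit=None,
) -> MarginalResult:
    """Marginal risk ratio between two exposure percentiles with a 95% CI."""
    if fit.design_info is None:
        raise ValueError("fit carries no design metadata; refit via fit_spline_logit")
    for p in (p_cmp, p_ref):
        _check_support(fit, data, p, strict)
    prob_cmp, grad_cmp = _prob_and_gradient(fit, data, p_cmp)
    prob_ref, grad_ref = _prob_and_gradient(fit, data, p_ref)
    if prob_ref <= 1e-300:
        raise ValueError("degenerate reference: marginal probability is numerically zero")
    rr = prob_cmp / prob_ref

    if p_cmp == p_ref:
        return MarginalResult(p_cmp, p_ref, prob_cmp, prob_ref, 1.0, 0.0, 1.0, 1.0, stratum, ci_method)

    z = norm.ppf(0.5 + level / 2.0)
    if ci_method == "delta":
        grad = grad_cmp / prob_cmp - grad_ref / prob_ref
        var = float(grad @ fit.vcov.to_numpy() @ grad)
        se = float(np.sqrt(max(var, 0.0)))
        lo, hi = np.exp(np.log(rr) - z * se), np.exp(np.log(rr) + z * se)
    elif ci_method == "bootstrap":
        if refit is None:
            raise ValueError("bootstrap CI needs a refit callable (data -> ModelFit)")
        rng = np.random.default_rng(boot_seed)
        clusters = data[cluster_col].unique()
        groups = {c: g for c, g in data.groupby(cluster_col)}
        log_rrs = []
        for _ in range(n_boot):
            chosen = rng.choice(clusters, size=len(clusters), replace=True)
            parts = [
                groups[c].assign(**{cluster_col: f"{c}__b{j}"}) for j, c in enumerate(chosen)
            ]
            bdf = pd.concat(parts, ignore_index=True)
            try:
                bfit = refit(bdf)
            except Exception:  # non-converged resample: skip, as a refit failure is
                continue  # uninformative about the sampling distribution
            num = marginal_probability(bfit, bdf, p_cmp)
            den = marginal_probability(bfit, bdf, p_ref)
            log_rrs.append(np.log(num / den))
        log_rrs = np.asarray(log_rrs)
        se = float(log_rrs.std(ddof=1))
        lo, hi = np.exp(np.quantile(log_rrs, [0.5 - level / 2.0, 0.5 + level / 2.0]))
    else:
        raise ValueError("ci_method must be 'delta' or 'bootstrap'")
    return MarginalResult(p_cmp, p_ref, prob_cmp, prob_ref, rr, se, float(lo), float(hi), stratum, ci_method)


def marginal_curve(fit: ModelFit, data: pd.DataFrame, grid=None) -> pd.DataFrame:
    """Marginal probability across a grid of exposure percentiles."""
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    grid = np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("empty percentile grid")
    with warnings.catch_warnings():
        # the curve is meant to sweep the full [0,1] range; the extrapolation
        # guard stays on for contrasts only
        warnings.simplefilter("ignore", UserWarning)
        probs = [marginal_probability(fit, data, float(p)) for p in grid]
    return pd.DataFrame({"percentile": grid, "marginal_probability": probs})


def interaction_test(fit: ModelFit, alpha: float = 0.05) -> InteractionTest:
    """Joint Wald chi-square test on the married x spline coefficients."""
    info = fit.design_info
    if info is None or not info.interaction_cols:
        raise ValueError("fit has no married x spline interaction terms")
    cols = info.interaction_cols
    b = fit.params[cols].to_numpy()
    V = fit.vcov.loc[cols, cols].to_numpy()
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular interaction vcov sub-block: {exc}") from exc
    df = len(cols)
    return InteractionTest(max(stat, 0.0), df, float(chi2.sf(max(stat, 0.0), df)), alpha)


def run_stratified(
    data: pd.DataFrame,
    fit_fn,
    fit_fn_interaction,
    contrasts=DEFAULT_CONTRASTS,
    by_country: bool = False,
    per_stratum_refits: bool = False,
    cluster_col: str = "site_id",
    outcome_col: str = "mobile",
) -> tuple[list[MarginalResult], dict[str, InteractionTest], list[str]]:
    """Gender-stratified marginal RRs, marital-status strata, optional countries.

    ``fit_fn(df)`` / ``fit_fn_interaction(df)`` fit the base and the
    married-interaction model on one gender's data. Marital-status stratum
    estimates come from the single interaction model evaluated over each
    group's rows (keeping the joint test coherent with the stratum
    estimates); ``per_stratum_refits`` switches to plain per-group fits as
    a sensitivity cross-check. Strata failing preconditions (one outcome
    class, <2 clusters) are skipped with a logged reason, never silently.
    """
    results: list[MarginalResult] = []
    tests: dict[str, InteractionTest] = {}
    skipped: list[str] = []

    def ok(df: pd.DataFrame, label: str) -> bool:
        if df[outcome_col].nunique() < 2:
            skipped.append(f"{label}: single outcome class")
            return False
        if df[cluster_col].nunique() < 2:
            skipped.append(f"{label}: fewer than 2 clusters")
            return False
        return True

    for gender in ("woman", "man"):
        gdf = data[data["gender"] == gender]
        glabel = {"woman": "women", "man": "men"}[gender]
        if len(gdf) == 0 or not ok(gdf, glabel):
            continue
        base = fit_fn(gdf)
        for p_cmp, p_ref in contrasts:
            results.append(marginal_rr(base, gdf, p_cmp, p_ref, stratum=glabel))

        inter = fit_fn_interaction(gdf)
        tests[glabel] = interaction_test(inter)
        for married_val, mlabel in ((True, "married"), (False, "unmarried")):
            sdf = gdf[gdf["married"] == married_val]
            label = f"{glabel}:{mlabel}"
            if len(sdf) == 0 or not ok(sdf, label):
                continue
            sfit = fit_fn(sdf) if per_stratum_refits else inter
            frame = sdf
            for p_cmp, p_ref in contrasts:
                results.append(marginal_rr(sfit, frame, p_cmp, p_ref, stratum=label))

        if by_country:
            for country, cdf in gdf.groupby("country"):
                label = f"{glabel}:{country}"
                if not ok(cdf, label):
                    continue
                cfit = fit_fn(cdf.assign(country=country))
                for p_cmp, p_ref in contrasts:
                    results.append(marginal_rr(cfit, cdf, p_cmp, p_ref, stratum=label))

    return results, tests, skipped


def results_frame(results: list[MarginalResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
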