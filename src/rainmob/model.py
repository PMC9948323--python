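"""Design construction and cluster-robust logistic regression.

The outcome model is a plain logistic regression of the binary mobility
indicator on a restricted-cubic-spline expansion of the rainfall
percentile, demographic covariates, country fixed effects and
survey-month indicators, with standard errors clustered at the
enumeration-area (site) level. Fitting is maximum likelihood by
Newton/IRLS; the clustered covariance is the CR1 sandwich

    V = B (sum_g s_g s_g') B * G/(G-1),   B = (X'WX)^{-1},
    s_g = X_g'(y_g - mu_g),

with CR0 (no finite-cluster factor) available by flag. Gender
stratification is always a fully separate fit, never a pooled
interaction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.special import expit

from .splines import SplineSpec, knots_from_quantiles, rcs_basis, select_knots

DEFAULT_COVARIATES = ("age", "wealth_q", "hh_size_cat", "education", "literate", "urban", "married")

_CATEGORICAL = {
    "wealth_q": {"ref": 1, "prefix": "wealth"},
    "hh_size_cat": {"ref": "1-2", "prefix": "hh"},
    "education": {"ref": "none", "prefix": "edu"},
}
_BINARY = ("literate", "urban", "married")


class SeparationError(RuntimeError):
    """Perfect separation: the MLE does not exist (coefficients diverge)."""


class RankDeficientError(ValueError):
    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear columns: {self.columns}")


@dataclass
class DesignInfo:
    """Everything needed to rebuild the design, including counterfactually."""

    spline: SplineSpec
    spline_cols: list[str]
    interaction_cols: list[str]
    covariates: tuple[str, ...]
    dummy_cols: dict[str, tuple[str, object]]  # column -> (variable, level)
    levels_seen: dict[str, list]
    include_country: bool
    include_month: bool
    include_interaction: bool


def _survey_month(df: pd.DataFrame) -> pd.Series:
    return pd.to_datetime(df["interview_date"]).dt.month


def build_design(
    df: pd.DataFrame,
    spec: SplineSpec,
    include_interaction: bool = False,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    include_country: bool = True,
    include_month: bool = True,
) -> tuple[pd.DataFrame, DesignInfo]:
    """Build the named design matrix for one model.

    Columns, in order: intercept; spline basis of the exposure percentile;
    the requested covariates (categoricals dummy-coded against fixed
    references: poorest wealth, household 1-2, no education); country
    indicators (reference = alphabetically first code); survey-month
    indicators (reference = January, or the earliest month present); and,
    if requested, married x spline interaction columns. Dummy columns are
    created for the levels present in the data; unseen levels at
    prediction time raise.
    """
    info = DesignInfo(
        spline=spec,
        spline_cols=spec.column_names(),
        interaction_cols=[f"married_x_{c}" for c in spec.column_names()] if include_interaction else [],
        covariates=tuple(covariates),
        dummy_cols={},
        levels_seen={},
        include_country=include_country,
        include_month=include_month,
        include_interaction=include_interaction,
    )

    def record_dummies(var: str, values: pd.Series, ref, prefix: str):
        levels = sorted(values.unique().tolist())
        info.levels_seen[var] = levels
        for lv in levels:
            if lv != ref:
                info.dummy_cols[f"{prefix}_{lv}"] = (var, lv)

    for var in covariates:
        if var in _CATEGORICAL:
            c = _CATEGORICAL[var]
            record_dummies(var, df[var], c["ref"], c["prefix"])
    if include_country:
        levels = sorted(df["country"].unique().tolist())
        info.levels_seen["country"] = levels
        for lv in levels[1:]:
            info.dummy_cols[f"country_{lv}"] = ("country", lv)
    if include_month:
        months = _survey_month(df)
        levels = sorted(months.unique().tolist())
        info.levels_seen["survey_month"] = levels
        ref = 1 if 1 in levels else levels[0]
        for lv in levels:
            if lv != ref:
                info.dummy_cols[f"month_{lv:02d}"] = ("survey_month", lv)

    return _encode(df, info), info


def _encode(df: pd.DataFrame, info: DesignInfo, percentile=None) -> pd.DataFrame:
    """Materialize the design matrix; ``percentile`` overrides the exposure."""
    n = len(df)
    p = df["percentile"].to_numpy(float) if percentile is None else np.full(n, float(percentile))
    basis = rcs_basis(p, info.spline)

    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    for j, name in enumerate(info.spline_cols):
        cols[name] = basis[:, j]
    if "age" in info.covariates:
        cols["age"] = df["age"].to_numpy(float)

    derived = {"survey_month": _survey_month(df) if info.include_month else None}
    for var, levels in info.levels_seen.items():
        values = derived[var] if var in derived and derived[var] is not None else df[var]
        unseen = set(values.unique()) - set(levels)
        if unseen:
            raise ValueError(f"unseen {var} level(s) at prediction time: {sorted(unseen)}")
    for col, (var, lv) in info.dummy_cols.items():
        values = derived[var] if var in derived and derived[var] is not None else df[var]
        cols[col] = (values == lv).to_numpy(float)
    for var in _BINARY:
        if var in info.covariates:
            cols[var] = df[var].to_numpy(float)
    if info.include_interaction:
        married = df["married"].to_numpy(float)
        for j, name in enumerate(info.interaction_cols):
            cols[name] = married * basis[:, j]
    return pd.DataFrame(cols, index=df.index)


def design_at_percentile(df: pd.DataFrame, info: DesignInfo, p: float) -> pd.DataFrame:
    """Counterfactual design with everyone's exposure percentile set to ``p``."""
    return _encode(df, info, percentile=p)


@dataclass
class ModelFit:
    """A converged cluster-robust logistic fit with named coefficients."""

    params: pd.Series
    vcov: pd.DataFrame
    vcov_naive: pd.DataFrame
    loglik: float
    n_obs: int
    n_clusters: int
    cr_type: str
    n_iter: int
    design_info: DesignInfo | None = None
    formula: str = ""

    @property
    def aic(self) -> float:
        return 2.0 * len(self.params) - 2.0 * self.loglik

    def se(self, robust: bool = True) -> pd.Series:
        v = self.vcov if robust else self.vcov_naive
        return pd.Series(np.sqrt(np.diag(v)), index=self.params.index)

    def conf_int(self, level: float = 0.95, robust: bool = True) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        se = self.se(robust)
        return pd.DataFrame(
            {"low": self.params - z * se, "high": self.params + z * se}, index=self.params.index
        )

    def to_json(self) -> str:
        payload = {
            "params": self.params.to_dict(),
            "columns": list(self.params.index),
            "vcov": self.vcov.to_numpy().tolist(),
            "vcov_naive": self.vcov_naive.to_numpy().tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "n_clusters": self.n_clusters,
            "cr_type": self.cr_type,
            "knots": list(self.design_info.spline.knots) if self.design_info else None,
            "formula": self.formula,
        }
        return json.dumps(payload, indent=2)


def fit_logistic(
    X,
    y,
    cluster_ids,
    cr_type: str = "CR1",
    max_iter: int = 100,
    tol: float = 1e-8,
    design_info: DesignInfo | None = None,
) -> ModelFit:
    """Maximum-likelihood logistic regression with a clustered sandwich.

    Newton/IRLS iterations with step-halving, run to an infinity-norm
    score below ``tol``. Raises on non-binary outcomes, rank-deficient
    designs (naming the collinear columns) and perfect separation.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(float)
    else:
        Xa = np.asarray(X, float)
        names = [f"x{j}" for j in range(Xa.shape[1])]
    ya = np.asarray(y, float)
    if not np.isin(ya, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if ya.min() == ya.max():
        raise SeparationError("degenerate outcome: all observations in one class")
    n, k = Xa.shape
    if len(ya) != n:
        raise ValueError("X and y length mismatch")
    codes, uniques = pd.factorize(np.asarray(cluster_ids))
    if len(codes) != n:
        raise ValueError("cluster_ids length mismatch")
    n_clusters = len(uniques)
    if cr_type not in ("CR0", "CR1"):
        raise ValueError("cr_type must be 'CR0' or 'CR1'")

    # rank check with column attribution
    _, R, piv = scipy.linalg.qr(Xa, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    thresh = max(n, k) * np.finfo(float).eps * (diag[0] if diag.size else 1.0)
    if diag.size == 0 or np.any(diag < thresh):
        bad = [names[j] for j in piv[np.flatnonzero(diag < thresh)]]
        raise RankDeficientError(bad or names)

    beta = np.zeros(k)
    eta = Xa @ beta

    def loglik_of(e):
        return float(np.sum(ya * e - np.logaddexp(0.0, e)))

    ll = loglik_of(eta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        grad = Xa.T @ (ya - mu)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        H = (Xa * w[:, None]).T @ Xa
        try:
            step = scipy.linalg.solve(H, grad, assume_a="pos")
        except scipy.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix at iteration {it}: {exc}") from exc
        # step-halving keeps the log-likelihood non-decreasing
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            ll_new = loglik_of(Xa @ cand)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * step
        eta = Xa @ beta
        ll = loglik_of(eta)
        if np.max(np.abs(beta)) > 1e4:
            raise SeparationError("coefficients diverging: data are perfectly separated")
    if not converged:
        mu = expit(eta)
        if np.min(mu * (1.0 - mu)) < 1e-12:
            raise SeparationError("fitted probabilities at 0/1: perfect separation suspected")
        raise RuntimeError(f"IRLS failed to converge in {max_iter} iterations")

    mu = expit(eta)
    if np.max(np.abs(eta)) > 25 and np.all(np.abs(ya - mu) < 1e-6):
        raise SeparationError("data are perfectly separated: all residuals vanish at saturated fit")
    w = mu * (1.0 - mu)
    H = (Xa * w[:, None]).T @ Xa
    bread = scipy.linalg.inv(H)
    scores = Xa * (ya - mu)[:, None]
    cluster_scores = np.zeros((n_clusters, k))
    np.add.at(cluster_scores, codes, scores)
    meat = cluster_scores.T @ cluster_scores
    factor = n_clusters / (n_clusters - 1.0) if (cr_type == "CR1" and n_clusters > 1) else 1.0
    vcov = bread @ meat @ bread * factor
    vcov = (vcov + vcov.T) / 2.0

    return ModelFit(
        params=pd.Series(beta, index=names),
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        vcov_naive=pd.DataFrame(bread, index=names, columns=names),
        loglik=ll,
        n_obs=n,
        n_clusters=n_clusters,
        cr_type=cr_type,
        n_iter=it,
        design_info=design_info,
    )


def fit_spline_logit(
    df: pd.DataFrame,
    knots: SplineSpec | int | str = "auto",
    include_interaction: bool = False,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    include_country: bool = True,
    include_month: bool = True,
    cr_type: str = "CR1",
    cluster_col: str = "site_id",
    outcome_col: str = "mobile",
) -> ModelFit:
    """Fit the mobility model on an assembled analysis frame.

    ``knots`` may be a :class:`SplineSpec`, an integer knot count (placed
    at the conventional quantiles of the observed exposure), or ``"auto"``
    for AIC selection over 3/4/5 knots (ties toward fewer).
    """
    x = df["percentile"].to_numpy(float)

    def fit_one(spec: SplineSpec) -> ModelFit:
        X, info = build_design(
            df, spec, include_interaction, covariates, include_country, include_month
        )
        return fit_logistic(X, df[outcome_col], df[cluster_col], cr_type, design_info=info)

    if isinstance(knots, SplineSpec):
        spec = knots
    elif isinstance(knots, int):
        spec = knots_from_quantiles(x, knots)
    elif knots == "auto":
        spec = select_knots(x, lambda s: fit_one(s).aic)
    else:
        raise ValueError(f"knots must be a SplineSpec, an int, or 'auto'; got {knots!r}")
    return fit_one(spec)
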