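"""Synthetic data with known ground truth.

Emulates the joint structure of a multi-country georeferenced household
survey linked to a gridded daily-precipitation product: a 31+ year daily
rainfall grid with a seasonal cycle and year-level anomalies, survey sites
(enumeration areas) nested in countries, respondents with demographic
covariates, and a binary short-term-mobility outcome whose logit may depend
on the site's true rainfall percentile through a U-shaped term.

The generating model for the outcome is

    logit P(mobile=1) = b0 + gamma * z(p) + delta * married * z(p)
                        + x'beta + u_site,      z(p) = 4 * (p - 1/2)^2,

with ``u_site ~ Normal(0, site_sd^2)``. ``z`` is 0 at the median percentile
and 1 at either extreme, so ``gamma`` is the log-odds difference between a
record-extreme year and a median year. ``true_marginal_rr`` integrates the
site intercepts out by Monte Carlo and is the oracle every
parameter-recovery test compares against.

All randomness flows from a single scenario seed through named
sub-streams, so each stage can be regenerated independently and every
operation is bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .grid import RainGrid

HH_SIZE_LEVELS = ["1-2", "3-4", "5-7", "8+"]
EDUCATION_LEVELS = ["none", "primary", "secondary", "higher"]

# Covariate distributions calibrated to the descriptive statistics of the
# DHS analysis sample (proportions renormalized to sum to 1).
_COVARIATE_TABLES = {
    "woman": {
        "age_mean": 28.5,
        "age_sd": 9.6,
        "hh_size": [0.070, 0.242, 0.401, 0.287],
        "wealth": [0.190, 0.185, 0.190, 0.206, 0.229],
        "education": [0.265, 0.379, 0.316, 0.039],
        "literate": 0.532,
        "married": 0.485,
    },
    "man": {
        "age_mean": 30.7,
        "age_sd": 11.8,
        "hh_size": [0.132, 0.226, 0.373, 0.279],
        "wealth": [0.183, 0.188, 0.195, 0.208, 0.227],
        "education": [0.153, 0.359, 0.415, 0.073],
        "literate": 0.665,
        "married": 0.448,
    },
}
URBAN_PROB = 0.38

#: numeric encodings used when covariate effects enter the outcome logit
_ENCODERS = {
    "age": lambda df: (df["age"].to_numpy(float) - 30.0) / 10.0,
    "wealth_q": lambda df: df["wealth_q"].to_numpy(float) - 3.0,
    "hh_size": lambda df: df["hh_size_cat"].map(
        {lv: i for i, lv in enumerate(HH_SIZE_LEVELS)}
    ).to_numpy(float) - 1.5,
    "education": lambda df: df["education"].map(
        {lv: i for i, lv in enumerate(EDUCATION_LEVELS)}
    ).to_numpy(float) - 1.0,
    "literate": lambda df: df["literate"].to_numpy(float),
    "married": lambda df: df["married"].to_numpy(float),
    "urban": lambda df: df["urban"].to_numpy(float),
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named deterministic sub-stream of a scenario seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(zlib.crc32(name.encode()),)))


def ushape(p) -> np.ndarray:
    """Quadratic exposure term z(p) = 4 (p - 0.5)^2, in [0, 1] on [0, 1]."""
    p = np.asarray(p, dtype=float)
    return 4.0 * (p - 0.5) ** 2


@dataclass
class DGPSpec:
    """Parameters of the synthetic data-generating process.

    ``baseline_logit`` defaults to logit(0.124), matching the observed
    mobility prevalence among women in the survey sample the generator
    emulates. ``covariate_betas`` maps covariate names (see module
    encoders) to log-odds effects; empty means no covariate effects.
    """

    seed: int = 0
    n_countries: int = 4
    sites_per_country: int = 100
    respondents_per_site: int = 100
    baseline_logit: float = float(logit(0.124))
    ushape_gamma: float = 0.0
    covariate_betas: Mapping[str, float] = field(default_factory=dict)
    site_sd: float = 0.3
    interaction_delta: float = 0.0
    women_frac: float = 0.5

    def __post_init__(self) -> None:
        if min(self.n_countries, self.sites_per_country, self.respondents_per_site) < 1:
            raise ValueError("counts must be >= 1")
        if self.site_sd < 0:
            raise ValueError("site_sd must be >= 0")
        unknown = set(self.covariate_betas) - set(_ENCODERS)
        if unknown:
            raise ValueError(f"unknown covariate_betas keys: {sorted(unknown)}")

    @property
    def n_sites(self) -> int:
        return self.n_countries * self.sites_per_country


def gen_rain_grid(
    seed: int,
    n_years: int = 31,
    n_cells_x: int = 8,
    n_cells_y: int = 8,
    seasonal_amplitude: float = 0.8,
    annual_mean_mm: float = 900.0,
    interannual_cv: float = 0.25,
    day_cv: float = 1.0,
    start_year: int = 1985,
    lon0: float = 10.0,
    lat0: float = -5.0,
    spacing: float = 0.05,
) -> RainGrid:
    """Generate a daily rainfall grid with seasonality and year-level anomalies.

    Daily depth = (annual_mean_mm / 365) * seasonal factor * year anomaly *
    day noise. The seasonal factor is a raised cosine with mean 1 over the
    year; the year anomaly is gamma-distributed per cell per calendar year
    with mean 1 and coefficient of variation ``interannual_cv``; day noise
    is gamma with mean 1 and CV ``day_cv`` (0 switches it off). Expected
    annual total per cell is therefore ~``annual_mean_mm``.
    """
    if n_years < 31:
        raise ValueError("insufficient lookback: need n_years >= 31 (30 prior years + survey year)")
    if annual_mean_mm <= 0:
        raise ValueError("annual_mean_mm must be > 0")
    if interannual_cv < 0 or day_cv < 0 or seasonal_amplitude < 0:
        raise ValueError("seasonal_amplitude, interannual_cv and day_cv must be >= 0")
    if seasonal_amplitude > 1:
        raise ValueError("seasonal_amplitude must be <= 1 to keep intensity non-negative")

    rng = substream(seed, "rain_grid")
    dates = np.arange(
        np.datetime64(f"{start_year}-01-01", "D"),
        np.datetime64(f"{start_year + n_years}-01-01", "D"),
    )
    n_days = dates.size
    n_cells = n_cells_y * n_cells_x

    doy = (dates - dates.astype("datetime64[Y]").astype("datetime64[D]")).astype(int)
    seasonal = 1.0 + seasonal_amplitude * np.cos(2.0 * np.pi * (doy - 15) / 365.25)
    base = annual_mean_mm / 365.0

    year_of_day = dates.astype("datetime64[Y]").astype(int) - np.datetime64(f"{start_year}", "Y").astype(int)
    if interannual_cv > 0:
        shape = 1.0 / interannual_cv**2
        anomalies = rng.gamma(shape, scale=1.0 / shape, size=(n_cells, n_years))
    else:
        anomalies = np.ones((n_cells, n_years))
    values = base * seasonal[None, :] * anomalies[:, year_of_day]

    if day_cv > 0:
        shape = 1.0 / day_cv**2
        values = values * rng.gamma(shape, scale=1.0 / shape, size=(n_cells, n_days))

    lon_axis = lon0 + spacing * np.arange(n_cells_x)
    lat_axis = lat0 + spacing * np.arange(n_cells_y)
    return RainGrid(lon_axis, lat_axis, dates, values.reshape(n_cells_y, n_cells_x, n_days))


def _draw_covariates(rng: np.random.Generator, gender: str, n: int) -> pd.DataFrame:
    tab = _COVARIATE_TABLES[gender]
    a = (15.0 - tab["age_mean"]) / tab["age_sd"]
    age = truncnorm.rvs(a, np.inf, loc=tab["age_mean"], scale=tab["age_sd"], size=n, random_state=rng)

    def cat(levels, probs):
        p = np.asarray(probs, float)
        return rng.choice(levels, size=n, p=p / p.sum())

    return pd.DataFrame(
        {
            "gender": gender,
            "age": age,
            "wealth_q": cat(np.arange(1, 6), tab["wealth"]),
            "hh_size_cat": cat(HH_SIZE_LEVELS, tab["hh_size"]),
            "education": cat(EDUCATION_LEVELS, tab["education"]),
            "literate": rng.random(n) < tab["literate"],
            "married": rng.random(n) < tab["married"],
        }
    )


def gen_survey(dgp: DGPSpec, grid: RainGrid) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place sites on the grid and draw respondents with covariates.

    Sites are uniform over the grid bounding box and split into contiguous
    longitude blocks, one block per country. Every respondent in a site
    shares the site's interview date (exposure is assigned at the
    enumeration-area level), drawn within the final 12 months of the grid
    span so a full 30-year lookback exists.
    """
    if grid.n_days == 0:
        raise ValueError("empty grid")
    if grid.n_days < 31 * 365:
        raise ValueError("grid must span at least 31 years for a 30-year lookback")

    rng = substream(dgp.seed, "survey")
    n_sites = dgp.n_sites
    lon = rng.uniform(grid.lon_axis[0], grid.lon_axis[-1], size=n_sites)
    lat = rng.uniform(grid.lat_axis[0], grid.lat_axis[-1], size=n_sites)
    order = np.argsort(lon, kind="stable")
    country = np.empty(n_sites, dtype=object)
    country[order] = np.repeat(
        [f"C{c:02d}" for c in range(dgp.n_countries)], dgp.sites_per_country
    )
    interview = grid.end_date - rng.integers(0, 365, size=n_sites).astype("timedelta64[D]")
    sites = pd.DataFrame(
        {
            "site_id": [f"S{i:05d}" for i in range(n_sites)],
            "lon": lon,
            "lat": lat,
            "country": country,
            "urban": rng.random(n_sites) < URBAN_PROB,
            "interview_date": pd.to_datetime(interview),
        }
    )

    m = dgp.respondents_per_site
    n_resp = n_sites * m
    gender = np.where(rng.random(n_resp) < dgp.women_frac, "woman", "man")
    parts = []
    for g in ("woman", "man"):
        mask = gender == g
        cov = _draw_covariates(rng, g, int(mask.sum()))
        cov.index = np.flatnonzero(mask)
        parts.append(cov)
    resp = pd.concat(parts).sort_index()
    resp.insert(0, "resp_id", [f"R{i:07d}" for i in range(n_resp)])
    resp.insert(1, "site_id", np.repeat(sites["site_id"].to_numpy(), m))
    site_cols = sites.set_index("site_id")
    resp["interview_date"] = resp["site_id"].map(site_cols["interview_date"])
    resp["urban"] = resp["site_id"].map(site_cols["urban"])
    return sites, resp.reset_index(drop=True)


def covariate_linear_predictor(respondents: pd.DataFrame, betas: Mapping[str, float]) -> np.ndarray:
    """x'beta for the outcome model, using the module's fixed encodings."""
    eta = np.zeros(len(respondents))
    for name, b in betas.items():
        eta += b * _ENCODERS[name](respondents)
    return eta


def site_intercepts(dgp: DGPSpec, site_ids) -> pd.Series:
    """One Normal(0, site_sd^2) intercept per site, keyed and seeded by site id order."""
    ids = sorted(set(site_ids))
    rng = substream(dgp.seed, "site_intercepts")
    return pd.Series(rng.normal(0.0, dgp.site_sd, size=len(ids)), index=ids)


def gen_outcome(
    dgp: DGPSpec, respondents: pd.DataFrame, true_percentiles: Mapping[str, float]
) -> pd.DataFrame:
    """Draw the binary mobility outcome from the generating logit."""
    p = respondents["site_id"].map(dict(true_percentiles))
    if p.isna().any():
        missing = respondents.loc[p.isna(), "site_id"].unique()
        raise ValueError(f"no true percentile for sites: {list(missing[:5])}")
    p = p.to_numpy(float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("true percentiles must lie in [0, 1]")

    z = ushape(p)
    married = respondents["married"].to_numpy(float)
    eta = (
        dgp.baseline_logit
        + dgp.ushape_gamma * z
        + dgp.interaction_delta * married * z
        + covariate_linear_predictor(respondents, dgp.covariate_betas)
        + respondents["site_id"].map(site_intercepts(dgp, respondents["site_id"])).to_numpy()
    )
    rng = substream(dgp.seed, "outcome")
    out = respondents.copy()
    out["mobile"] = (rng.random(len(out)) < expit(eta)).astype(int)
    return out


def gen_site_percentiles(seed: int, site_ids) -> dict[str, float]:
    """Site-level true percentiles, Uniform(0,1) — the stationary-climate limit."""
    ids = list(site_ids)
    rng = substream(seed, "site_percentile")
    return dict(zip(ids, rng.uniform(0.0, 1.0, size=len(ids))))


def true_marginal_rr(
    dgp: DGPSpec,
    respondents: pd.DataFrame,
    p_cmp: float,
    p_ref: float,
    n_mc: int = 100_000,
) -> float:
    """Ground-truth marginal risk ratio implied by the generating process.

    Averages, over the respondents' observed covariates and over Monte-Carlo
    draws of the site intercept, the event probability with the exposure
    percentile forced to ``p_cmp``, divided by the same at ``p_ref``.
    Exact (no Monte Carlo) when ``site_sd`` is 0.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    for p in (p_cmp, p_ref):
        if not 0.0 <= p <= 1.0:
            raise ValueError("contrast percentiles must lie in [0, 1]")

    married = respondents["married"].to_numpy(float)
    base = dgp.baseline_logit + covariate_linear_predictor(respondents, dgp.covariate_betas)

    def mean_prob(p_star: float) -> float:
        z = float(ushape(p_star))
        eta = base + (dgp.ushape_gamma + dgp.interaction_delta * married) * z
        if dgp.site_sd == 0:
            return float(np.mean(expit(eta)))
        u = substream(dgp.seed, "truth_mc").normal(0.0, dgp.site_sd, size=n_mc)
        vals, counts = np.unique(eta, return_counts=True)
        # E_u expit(a + u) per distinct linear predictor, chunked over u
        acc = np.zeros_like(vals)
        step = max(1, int(2e7) // max(vals.size, 1))
        for i in range(0, n_mc, step):
            acc += expit(vals[:, None] + u[None, i : i + step]).sum(axis=1)
        return float(np.average(acc / n_mc, weights=counts))

    denom = mean_prob(p_ref)
    if denom <= 0:
        raise ValueError("degenerate reference probability")
    return mean_prob(p_cmp) / denom


def calibrate_ushape_gamma(
    target_rr: float,
    dgp: DGPSpec,
    respondents: pd.DataFrame | None = None,
    p_cmp: float = 0.15,
    p_ref: float = 0.5,
    n_mc: int = 200_000,
) -> float:
    """Solve for the U-shape coefficient giving a target true marginal RR.

    With no site heterogeneity and no covariate effects the solution is the
    closed form gamma = (logit(target * expit(b0)) - b0) / z(p_cmp); otherwise
    the truth oracle is inverted numerically.
    """
    z = float(ushape(p_cmp))
    p0 = float(expit(dgp.baseline_logit))
    closed = (float(logit(target_rr * p0)) - dgp.baseline_logit) / z
    if respondents is None or (dgp.site_sd == 0 and not dgp.covariate_betas):
        return closed

    def f(g: float) -> float:
        d = DGPSpec(**{**dgp.__dict__, "ushape_gamma": g})
        return true_marginal_rr(d, respondents, p_cmp, p_ref, n_mc=n_mc) - target_rr

    return float(brentq(f, 0.0, max(4 * closed, 0.5), xtol=1e-6))
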