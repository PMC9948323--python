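"""End-to-end pipeline: rainfall grid -> survey -> exposure -> models -> margins.

A :class:`RunConfig` fully determines a run — the same config produces a
byte-identical report payload (timestamps live outside the hashed part).
Stages: synthetic grid and survey generation, exposure-percentile
construction, complete-case validation, gender-stratified spline logistic
fits, marginal risk ratios with the marital-status interaction test, and
marginal probability curves. All artifacts are written under the
configured output directory; the report is machine-readable JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exposure import assemble_analysis_frame, build_exposure_table
from .margins import DEFAULT_CONTRASTS, marginal_curve, results_frame, run_stratified
from .model import DEFAULT_COVARIATES, fit_spline_logit
from .synthetic import DGPSpec, gen_outcome, gen_rain_grid, gen_survey

log = logging.getLogger("rainmob")

REQUIRED_COVARIATES = (
    "age",
    "wealth_q",
    "hh_size_cat",
    "education",
    "literate",
    "married",
    "urban",
    "interview_date",
)


@dataclass
class RunConfig:
    """Complete configuration of one pipeline run."""

    seed: int = 0
    dgp: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    link_method: str = "nearest"
    percentile_convention: str = "midrank"
    knots: int | str = "auto"
    interaction: bool = True
    covariates: tuple = DEFAULT_COVARIATES
    contrasts: tuple = DEFAULT_CONTRASTS
    ci_method: str = "delta"
    by_country: bool = False
    outdir: str = "results/run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.covariates = tuple(cfg.covariates)
        cfg.contrasts = tuple(tuple(c) for c in cfg.contrasts)
        return cfg

    def dgp_spec(self) -> DGPSpec:
        return DGPSpec(seed=self.seed, **self.dgp)

    def payload(self) -> dict:
        d = asdict(self)
        d.pop("outdir")
        return d

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(self.payload(), sort_keys=True, default=str).encode()).hexdigest()[:16]


def validate_inputs(sites: pd.DataFrame, respondents: pd.DataFrame, grid) -> tuple[pd.DataFrame, dict]:
    """Complete-case filter plus coverage/lookback diagnostics.

    Returns the respondents retained for modelling and a report listing
    every dropped row and uncovered site; only respondents with full
    covariate (and, when present, outcome) data are kept.
    """
    report: dict = {}
    cols = [c for c in REQUIRED_COVARIATES if c in respondents.columns]
    if "mobile" in respondents.columns:
        cols.append("mobile")
    missing_mask = respondents[cols].isna().any(axis=1)
    report["n_input"] = int(len(respondents))
    report["n_dropped_missing"] = int(missing_mask.sum())
    report["dropped_missing_ids"] = respondents.loc[missing_mask, "resp_id"].tolist()[:200]

    uncovered = [
        row["site_id"]
        for _, row in sites.iterrows()
        if not grid.contains(float(row["lon"]), float(row["lat"]))
    ]
    report["sites_without_coverage"] = uncovered

    from .exposure import N_HISTORY, _shift_years

    no_lookback = []
    for sid, date in respondents[["site_id", "interview_date"]].dropna().drop_duplicates().itertuples(index=False):
        earliest = _shift_years(pd.Timestamp(date), N_HISTORY) - pd.Timedelta(days=365)
        if grid.day_index(earliest) < 0:
            no_lookback.append((sid, str(pd.Timestamp(date).date())))
    report["pairs_without_lookback"] = no_lookback

    keep = respondents[~missing_mask & ~respondents["site_id"].isin(uncovered)].copy()
    report["n_retained"] = int(len(keep))
    return keep, report


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write artifacts + a JSON report to ``outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    dgp = config.dgp_spec()

    log.info("stage 1/5: rainfall grid")
    grid = gen_rain_grid(config.seed, **config.grid)

    log.info("stage 2/5: survey generation (%d sites)", dgp.n_sites)
    sites, respondents = gen_survey(dgp, grid)

    log.info("stage 3/5: exposure table")
    exposure = build_exposure_table(
        grid, sites, respondents, method=config.link_method, convention=config.percentile_convention
    )
    pmap = dict(zip(exposure["site_id"], exposure["percentile"]))
    respondents = gen_outcome(dgp, respondents, pmap)

    respondents, validation = validate_inputs(sites, respondents, grid)
    frame = assemble_analysis_frame(sites, respondents, exposure)

    sites.to_csv(out / "sites.csv", index=False)
    respondents.to_csv(out / "respondents.csv", index=False)
    exposure.to_csv(out / "exposure.csv", index=False)

    log.info("stage 4/5: spline logistic fits per gender")

    def fit_base(df):
        return fit_spline_logit(df, knots=config.knots, covariates=config.covariates)

    def fit_inter(df):
        return fit_spline_logit(
            df, knots=config.knots, include_interaction=True, covariates=config.covariates
        )

    results, tests, skipped = run_stratified(
        frame, fit_base, fit_inter, contrasts=config.contrasts, by_country=config.by_country
    )
    for reason in skipped:
        log.warning("stratum skipped: %s", reason)

    log.info("stage 5/5: marginal curves")
    curves = {}
    fit_summaries = {}
    for gender, glabel in (("woman", "women"), ("man", "men")):
        gdf = frame[frame["gender"] == gender]
        if len(gdf) == 0 or gdf["mobile"].nunique() < 2:
            continue
        fit = fit_base(gdf)
        curve = marginal_curve(fit, gdf, np.linspace(0.0, 1.0, 51))
        curve.insert(0, "gender", glabel)
        curves[glabel] = curve
        fit_summaries[glabel] = {
            "n_obs": fit.n_obs,
            "n_clusters": fit.n_clusters,
            "aic": fit.aic,
            "loglik": fit.loglik,
            "knots": list(fit.design_info.spline.knots),
        }
    if curves:
        pd.concat(curves.values()).to_csv(out / "marginal_curves.csv", index=False)
        _plot_curves(curves, out / "marginal_curves.png")

    rframe = results_frame(results)
    rframe.to_csv(out / "marginal_results.csv", index=False)

    payload = {
        "config_hash": config.hash(),
        "config": config.payload(),
        "versions": {"rainmob": __version__, "python": sys.version.split()[0]},
        "validation": validation,
        "prevalence": {
            glabel: float(frame.loc[frame["gender"] == g, "mobile"].mean())
            for g, glabel in (("woman", "women"), ("man", "men"))
            if (frame["gender"] == g).any()
        },
        "exposure_summary": {
            "mean_percentile": float(exposure["percentile"].mean()),
            "sd_percentile": float(exposure["percentile"].std()),
        },
        "fits": fit_summaries,
        "marginal_results": rframe.to_dict(orient="records"),
        "interaction_tests": {k: t.to_dict() for k, t in tests.items()},
        "skipped_strata": skipped,
    }
    report = {"generated_at": datetime.now(timezone.utc).isoformat(), **payload}
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _plot_curves(curves: dict, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for glabel, curve in curves.items():
        ax.plot(curve["percentile"], curve["marginal_probability"], label=glabel)
    ax.set_xlabel("rainfall percentile deviation")
    ax.set_ylabel("marginal probability of short-term mobility")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
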