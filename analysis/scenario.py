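"""Shared scenario for the numbered analysis scripts.

A mid-sized survey: 4 countries x 75 sites x 120 respondents (~36,000
people, half women), a 31-year 8x8 rainfall grid, U-shaped exposure
effect among married respondents calibrated near the survey-scale effect
size, and site-level heterogeneity of 0.3 on the logit scale.
"""

from pathlib import Path

from scipy.special import logit

from rainmob.pipeline import RunConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"
SEED = 20260919


def make_config() -> RunConfig:
    return RunConfig(
        seed=SEED,
        dgp=dict(
            n_countries=4,
            sites_per_country=75,
            respondents_per_site=120,
            baseline_logit=float(logit(0.124)),
            ushape_gamma=0.0,
            interaction_delta=0.24,
            site_sd=0.3,
            women_frac=0.5,
            covariate_betas={"urban": -0.15, "literate": 0.1, "age": -0.1},
        ),
        grid=dict(n_cells_x=8, n_cells_y=8),
        knots="auto",
        outdir=str(RESULTS),
    )
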