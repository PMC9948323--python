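# rainmob

Rainfall-anomaly exposures and short-term human mobility: a tested,
reusable pipeline for linking gridded daily precipitation to georeferenced
household-survey clusters and estimating how deviations from a location's
own rainfall history relate to the probability of having spent more than a
month away from home in the past year.

The package is aimed at environmental epidemiologists and demographers
working with DHS-style surveys (geocoded enumeration areas, binary
mobility outcomes, standard demographic covariates) joined to CHIRPS-style
precipitation rasters. Because such microdata are restricted-access, the
package ships a first-class synthetic generator with a known
data-generating process and a Monte-Carlo truth oracle, so every stage of
the analysis is verifiable against ground truth.

## The method

**Exposure.** For each enumeration area (EA) and interview date, rainfall
is summed over the 365 days preceding the interview and ranked against the
same window shifted back 1..29 whole years at that EA. With midranks for
ties, the percentile is (rank − 1)/29 within the pooled 30-value record:
0 = driest year on record locally, 1 = wettest, 0.5 = the pooled median.
Both tails of this *rainfall percentile deviation* are of interest —
drought (p = 0.15) and heavy rain (p = 0.85) versus the median (p = 0.50).

**Model.** Mobility is modelled per gender by logistic regression

&nbsp;&nbsp;logit P(mobile) = f(p; **θ**) + x'β + country FE + month FE,

where f is a restricted cubic spline in the percentile (knot count chosen
by AIC over 3/4/5 knots at conventional quantile placements), x holds age,
wealth quintile, household-size and education categories, literacy, urban
and marital status, and standard errors are clustered at the EA level
(CR1 sandwich, G/(G−1) scaling).

**Inference.** Marginal standardization (g-computation): everyone's
exposure is counterfactually set to p, predictions averaged over the
observed covariate distribution, and contrasts reported as marginal risk
ratios with delta-method CIs on log RR through the clustered covariance
(seeded cluster bootstrap available as a cross-check). Effect modification
by marital status is a joint Wald chi-square test on the married × spline
interaction block, with marital-stratum RRs evaluated from the same
interaction model.

## Worked example

The numbered scripts under `analysis/` run a complete scenario (4
countries × 75 sites × 120 respondents on a 31-year 8×8 grid, U-shaped
exposure effect carried by married respondents, site-intercept SD 0.3):

```bash
cd analysis
python 01_simulate.py && python 02_exposure.py
python 03_fit_models.py && python 04_margins.py
```

which prints, among other things:

```
percentile mean 0.534, sd 0.340 (uniform reference: 0.500, 0.293)
women: n=18038, clusters=300, prevalence 0.134, knots=[0.034, 0.517, 1.0], AIC=14118.9
             women RR(0.15 vs 0.50) = 1.145 (1.049-1.250)
     women:married RR(0.15 vs 0.50) = 1.250 (1.115-1.400)
   women:unmarried RR(0.15 vs 0.50) = 1.048 (0.930-1.182)
women: joint interaction Wald chi2(2) = 14.40, p = 0.0007
```

Read: exposure percentiles are near-uniform (stationary climate); women's
mobility prevalence is 13.4%; living at the 15th rainfall percentile
rather than the median raises the marginal probability of mobility by
14.5% overall in this scenario, concentrated among married women (+25.0%,
versus +4.8% among unmarried women) — and the joint test detects that
effect modification. `05_calibration_study.py` replays the estimator over
replicates and reports bias against the truth oracle and CI coverage.

The same run is available end-to-end as a library call
(`rainmob.run_pipeline(RunConfig(...))`) or from the shell
(`rainmob all --config cfg.yaml`).

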