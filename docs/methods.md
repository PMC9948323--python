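# Methods

## Exposure construction

The exposure is a *relative* rainfall anomaly: each site's 12-month
pre-interview rainfall is compared only with that same site's history, so
wet and dry climates are on a common [0, 1] scale.

Conventions (the underlying survey-linkage literature rarely states
these, so they are declared here rather than inferred):

- **Window**: 365 days, half-open, ending the day *before* the interview
  — the interview day is excluded. Historical windows are the same span
  shifted back 1..29 whole calendar years (shift first, clamp Feb 29 to
  Feb 28), which keeps seasonal alignment.
- **Percentile**: pool the current value with the 29 historical values,
  rank ascending, give ties the mean of their tied ranks, and map rank r
  to (r − 1)/29. A record minimum is 0, a record maximum is 1, and the
  pooled median maps to 0.5. Hazen ((r − 0.5)/30) and Weibull (r/31)
  plotting positions are available behind the `convention` flag; they
  compress the extremes slightly and are provided for sensitivity
  analysis only.
- **Raster linkage**: nearest cell by great-circle distance (default);
  at a 0.05° grid spacing the cell is small relative to typical EA
  geomasking displacement, so bilinear interpolation (also provided)
  changes percentiles negligibly.
- **Missing rainfall days are never imputed**: a window not fully covered
  by the grid raises an error listing the offending site/date pairs,
  rather than silently biasing a sum.

The percentile is invariant under any strictly monotone transformation of
all 30 sums, and on a stationary climate is uniform on the 30-point grid
{0, 1/29, ..., 1} — the tests verify both, the latter with a
Monte-Carlo-calibrated Kolmogorov–Smirnov test (the discrete support
alone would otherwise trip the continuous KS formula at n ≈ 2,000).

## Synthetic generating process

`gen_rain_grid` produces daily rainfall as

    mm(cell, day) = (annual_mean / 365) · season(doy) · A(cell, year) · ε(cell, day)

with `season` a raised cosine (amplitude ≤ 1, mean 1 over the year),
`A` gamma-distributed per cell-year with mean 1 and coefficient of
variation `interannual_cv` (default 0.25), and `ε` gamma day-noise with
CV `day_cv` (default 1, giving realistically spiky daily totals). The
multiplicative year-level anomaly makes "driest year on record"
well-defined and produces right-skewed annual totals. Not emulated:
spatial covariance between cells, real geography, within-year anomaly
persistence. Passing tests therefore demonstrate correctness of the
*method* under a stationary, spatially independent climate — not
robustness to trends or spatially correlated droughts.

`gen_survey` draws sites uniformly over the grid with countries as
contiguous longitude blocks, one interview date per site in the final 12
months (exposure is assigned at the EA level: everyone in a site shares
date and percentile), and covariates from gender-specific distributions
calibrated to a large multi-country survey sample (urban 38%, married
48.5%/44.8%, literate 53.2%/66.5%, truncated-normal ages ≥ 15, etc.).

The outcome follows

    logit P(mobile) = b0 + γ·z(p) + δ·married·z(p) + x'β + u_site,
    z(p) = 4(p − ½)²,  u_site ~ N(0, site_sd²)

so γ is the log-odds gap between a record-extreme and a median rainfall
year, and δ (the effect-modification parameter) acts on the same
quadratic term — the simplest process that yields marital-status effect
modification. `b0` defaults to logit(0.124), the women's mobility
prevalence in the emulated sample. `site_sd` defaults to 0.3 on the logit
scale (latent ICC ≈ 0.027), a moderate within-EA correlation chosen once
as typical for clustered binary survey outcomes; the real within-EA
correlation of mobility is unknown. The U-shape is symmetric by
construction; real exposure-response curves need not be.

`true_marginal_rr` is the truth oracle: it averages event probabilities
over the respondents' observed covariates, integrating the site intercept
out by seeded Monte Carlo (exact closed form when `site_sd` = 0), with
exposure forced to each contrast percentile. `calibrate_ushape_gamma`
inverts it to hit a target true RR, e.g. 1.055 at the drought contrast.

All randomness flows from one scenario seed through named sub-streams
(CRC-derived spawn keys), so any stage can be regenerated independently
and byte-identically.

## Model fitting

Maximum likelihood by Newton/IRLS with step-halving, run to an
infinity-norm score below 1e-8; the log-likelihood is non-decreasing
across iterations by construction. Perfect separation is detected (and
raised) three ways: one-class outcomes, diverging coefficients, and
saturated fits with vanishing residuals. Rank-deficient designs raise
with the names of the collinear columns (QR with pivoting).

The clustered covariance is the CR1 sandwich — bread = inverse observed
information, meat = sum of within-cluster score outer products, scaled by
G/(G−1). CR0 omits the scaling. (Some packages additionally apply
(n−1)/(n−k); with hundreds of clusters and few parameters the difference
is negligible, and the cross-check test against an independent GLM
implementation is run at CR0 where the conventions coincide exactly.)

Spline knots sit at conventional quantiles of the observed exposure
(10/50/90 for 3 knots; 5/35/65/95 for 4; 5/27.5/50/72.5/95 for 5); AIC
chooses the count, ties breaking toward fewer knots. Reference categories
are fixed and documented: poorest wealth quintile, household size 1–2, no
education, alphabetically first country, January (or earliest present)
survey month. Gender stratification is always two fully separate fits.
Survey-month indicators are retained in every model: seasonal mobility
would otherwise be partially absorbed by the rainfall anomaly, whose
window is anchored at the interview date.

## Marginal inference

Marginal probabilities are g-computation averages: the spline (and
married × spline) columns are re-evaluated at the counterfactual
percentile, all other columns kept as observed, predictions averaged.
Risk ratios are ratios of these averages; CIs come from the delta method
on log RR with gradient (A_cmp/P_cmp − A_ref/P_ref), A = mean of
μ(1−μ)·x over counterfactual rows, propagated through the clustered
covariance. A seeded cluster bootstrap (sites resampled with replacement,
model refit, percentile interval) is the verification alternative;
non-converged resamples are skipped. Contrasts outside the observed
exposure support warn by default and raise under strict mode.

Marital-status stratum estimates are evaluated from the single
interaction model over each stratum's rows, keeping the joint Wald test
(on the married × spline coefficient block, chi-square with one degree of
freedom per interaction column) coherent with the stratum estimates;
independent per-stratum refits are available as a sensitivity flag.

## Calibration studies and problem sizes

The replicated studies in `rainmob.experiments` draw each site's true
percentile directly from Uniform(0, 1) — the stationary-climate limit
verified for the exposure stage — rather than regenerating a 31-year
daily grid per replicate; the grid → exposure path is exercised
end-to-end by the pipeline and its tests. Study sizes were chosen by
power calculation before running: recovery and coverage use 400 sites ×
100 respondents (site_sd 0.3) with 50 replicates; null calibration uses
1,000 sites × 100 (n = 100,000) with 100 replicates; the U-shape
reproduction study uses 600 sites × 150 with site_sd 0.15 and the
exposure effect calibrated via the truth oracle to a true RR of 1.055,
where the per-replicate standard error (~0.02 on log RR) makes an
above-one estimate a near-certain event per contrast.

Two findings from these studies are worth knowing:

- A 3-knot restricted spline cannot represent the symmetric quadratic
  truth (one nonlinear basis column), biasing the drought log-RR by
  ~+0.045 at γ = 0.5; a 5-knot basis is effectively unbiased
  (≤ 0.006). The recovery study therefore uses the 5-knot basis.
- Per-replicate AIC knot selection reintroduces undercoverage
  (~0.80–0.90 against the nominal 0.95) through post-model-selection
  variability that the delta CIs do not account for — a known limitation
  of select-then-estimate inference, independent of effect size. Treat
  reported CIs after AIC selection as slightly anti-conservative.

## Known limitations

- No spatial covariance in the synthetic climate; no DHS two-stage
  sampling weights (the emulated analyses do not use them); no
  drought-index families (SPI/SPEI) or sub-annual windows.
- Effect modification enters only through the quadratic exposure term, so
  marital strata share the location of the curve's minimum; differential
  asymmetric responses (e.g., one stratum reacting only to heavy rain)
  are outside this generating process.
- The current-year window and year-shifted historical windows each mix
  two calendar-year anomalies, making consecutive windows weakly
  dependent (moving-average structure); empirically this does not
  disturb percentile uniformity at the tested scale.
- Complete-case analysis only; validation reports dropped rows but no
  imputation is offered.
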