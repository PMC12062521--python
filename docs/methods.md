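# Methods

## The problem

Serum neurofilament light chain (sNfL) is a blood biomarker of axonal
injury. Its concentration in healthy adults is right-skewed at any age and
rises roughly exponentially with age, so clinical interpretation needs
age- (and ideally sex-) specific reference limits rather than a single
cut-off. This package implements the three estimators such a reference
study uses — crude nonparametric intervals, a closed-form log-linear upper
limit, and BCCG/LMS centile curves — together with a synthetic cohort
generator that stands in for subject-level data, which reference studies
rarely release.

## Synthetic cohort generator

`SimulationConfig` draws a cohort with:

- **Age structure**: fixed counts per 10-year bin, default
  `{20: 57, 30: 58, 40: 59, 50: 37, 60: 12}` (223 subjects), ages
  continuous-uniform within each bin. Recruitment nominally spans 18–70
  years but the default bins start at 20; the CSV reader nevertheless
  accepts 18–70, mirroring the mismatch between recruitment window and
  reporting strata that real studies show.
- **Sex**: independent Bernoulli draws with `female_fraction = 127/223`,
  or an exact split via `fixed_sex_counts` when the totals must be pinned.
- **Concentration**: BCCG(μ(age, sex), σ, ν) with
  `μ = mu_scale · 10^(mu_log10_slope·age) · female_mu_ratio^[female]`.
  Defaults `mu_scale = 2.1` pg/ml, `mu_log10_slope = 0.012`/yr,
  `female_mu_ratio = 0.873`, `σ = 0.38`, `ν = 0.3`. These were calibrated
  once so that simulated decade medians run from ≈3.6 pg/ml (20s) to
  ≈12 pg/ml (60s), females sit ≈1 pg/ml below males, and the log10-scale
  residual spread is ≈0.166 (`σ/ln 10` for small ν) — the distributional
  fingerprint of a healthy adult sNfL cohort.

Sampling is inverse-CDF on a standard normal draw; draws with
`1 + σνz ≤ 0` (probability < 1e-4 at the defaults) are rejected and
redrawn, so the generator samples the truncated distribution exactly. All
randomness flows through one `numpy` generator seeded from the config.
`true_centile` exposes the generating quantiles so fitters can be tested
for parameter recovery.

What the generator does **not** emulate: assay noise and plate effects,
BMI/renal/metabolic covariates, non-log-linear age trends, and
age-dependent σ or ν. Passing recovery tests therefore show that the
estimators are correct under the stated model, not that the model captures
every feature of real sNfL data.

## Nonparametric reference intervals

Percentiles use the rank `r = p(n+1)` with linear interpolation between
order statistics and clamping to the extremes (numpy's `weibull` method) —
the convention of the CLSI EP28 nonparametric procedure. Which
interpolation rule (if any) a given published interval used is usually
unstated; this one is fixed here and tested against a brute-force oracle.
Strata with n < 120 are estimated anyway and flagged, since real studies
report decade strata with n as low as 12. Median CIs use the percentile
bootstrap (default 2 000 resamples of the raw values, seeded). The
Mann-Whitney test uses the exact permutation null when min(n) ≤ 8 without
ties — where enumeration is cheap — and the tie-corrected normal
approximation with continuity correction otherwise.

## Log10-linear cut-off

OLS of `log10(sNfL)` on age and a female indicator (female = 1). The
`residual_se` is the residual standard deviation with n − 3 degrees of
freedom; the term "standard error of the model" in the reference-study
literature is taken to mean this quantity. Coefficient p-values come from
the t distribution. The predicted 97.5th percentile adds `z·s` (default
z = 1.96, configurable) to the linear predictor; exponentiating gives the
multiplicative form `scale · age_factor^age · female_factor^[female]` with
`scale = 10^(b0 + z·s)`. Note that reconstructing a published scale
constant from rounded coefficients carries ~0.3% slack: with the frozen
fit shipped here, `10^(0.326 + 1.96·0.166) = 4.4816` versus a printed
4.470 computed from unrounded coefficients.

## BCCG distribution and centile model

BCCG(μ, σ, ν): `z = ((y/μ)^ν − 1)/(νσ)` is standard normal; `ν = 0` is
the log-normal limit, entered when |ν| ≤ 1e-5 (the two branches agree to
~1e-10 there). The Cole-Green construction strictly speaking truncates z
at `−1/(σν)`; when the attainable-z mass `Φ(1/(σ|ν|))` exceeds 1 − 1e-3
(always the case for biomarker-scale σ ≈ 0.4, ν ≈ 0.3) the plain formulas
are used, as in the original LMS work. Below that threshold the density is
renormalized and the CDF/quantile adjusted accordingly, so the
distribution functions stay mutually consistent over the whole parameter
space; in this regime μ is the median of the untruncated construction, not
of the truncated law.

The centile model gives each parameter a fixed-knot regression-spline
predictor in age: log link for μ and σ, identity for ν. The requested
degrees of freedom set the basis dimension (1 = constant, 2 = linear,
k ≥ 3 a B-spline of degree min(3, k−1) with interior knots at age
quantiles). Defaults — df 3 for μ, constants for σ and ν — reflect what a
~200-subject cohort can support; since μ is fit on a log link and the
generating median is log-linear in age, the default basis nests the truth.
Regression splines with integer df were chosen over a ridge-penalized
smoother with matched effective df: the fit is then a pure maximum
likelihood problem, deterministic, with nothing to tune.

Fitting cycles over μ, σ, ν in Rigby–Stasinopoulos fashion: each parameter
takes a Fisher-scoring weighted-least-squares update on its own predictor
(expected-information weights `(1 + 2σ²ν²)/σ²`, `2`, and `7σ²/4`
respectively), with step halving so the log-likelihood never decreases,
until the relative change falls below 1e-6 (max 200 cycles; exceeding
them raises an error carrying the iteration trace). Initial values: μ from
OLS of log y on the μ basis, σ from the residual spread, ν = 1 (the
classic LMS start). On the default data the fit converges in ~5 cycles.

Sex is handled by fitting each sex stratum separately (default, ≥ 30
subjects per stratum required) or by one pooled fit; both modes exist
because published centile figures are sometimes pooled and sometimes
stratified. Prediction outside the observed age range is refused unless
`extrapolate=True` — estimates beyond the data (especially above age 50,
where reference cohorts thin out) are imprecise, and silent extrapolation
would hide that.

Z-scores apply the z-transform at each subject's age/sex parameters; the
implied percentile is `Φ(z)`. The exceedance summary reports the fractions
with |Z| > 1.96 and Z > 1.96 (nominally 5% and 2.5% under a calibrated
model). Models serialize to JSON as knot vectors plus coefficients at full
double precision, so a reloaded model reproduces predictions to 1e-12.

## Numerical and validation choices

- Problem sizes in the tests: parameter recovery uses 2 000 subjects per
  sex (μ within 5% over ages 20–60); band-coverage checks fit on 5 000 and
  evaluate on an independent 50 000 (95% ± 1 percentage point); ν, the
  noisiest parameter (sampling error ~20% at n = 2 000/sex), is checked
  at 15% on a 20 000-subject stratum. These sizes keep every check's
  sampling error several times smaller than its tolerance.
- Quantile/Z/CDF roundtrips are asserted to 1e-9, density normalization by
  quadrature to 1e-4.
- Degenerate inputs: empty samples, single-sex cohorts, constant data,
  out-of-range ages and non-positive concentrations all raise or flag
  explicitly; validation never silently drops rows without a recorded
  reason.

## Known limitations

- σ and ν are constant in age by default; real sNfL data may show
  age-varying spread, which the defaults would smooth over (raise
  `edf_sigma`/`edf_nu` to model it).
- The bootstrap is the simple percentile method; BCa intervals would have
  better small-sample coverage for skewed data.
- No covariates beyond age and sex (BMI, creatinine, HbA1c are known
  correlates of sNfL but are out of scope).
- The generator's log-linear μ cannot emulate the steeper post-50 rise
  some cohorts describe; conclusions about extreme-age behaviour should
  not be drawn from it.
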