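# Methods

## Reference-chart model

For a response `y` (Dmax mm, Dmin mm, or diameter distensibility DD as a
dimensionless fraction) and a single predictor `x` (gestational age GA in
weeks, biparietal diameter BPD in mm, or femur length FL in mm), a chart is

    μ(x) = Σ_k β_k x^k        (k ⊆ {0,1,2,3})
    σ(x) = a + b x            (σ > 0 over the chart's predictor range)
    z    = (y − μ(x)) / σ(x)

with Gaussian residuals assumed throughout — no LMS/GAMLSS
skewness–kurtosis modelling, and strictly one predictor at a time. The
central 90% reference band is |z| ≤ 1.65 (strict inequality flags
outside); percentile curves use the exact quantile Φ⁻¹(0.95) = 1.6449, so
the printed clinical threshold 1.65 and the percentile arithmetic are kept
deliberately distinct.

DD is stored and computed as a fraction; percent is presentation only
(`distensibility_percent`). The published coefficient magnitudes
(means ≈ 0.07–0.47, SDs ≈ 0.04–0.14) are on the fraction scale despite
"(100%)" labels in their source, and scoring is scale-invariant anyway.

## Chart construction (three steps)

1. **Mean model.** OLS of `y` on each candidate power set (all subsets of
   {1,2,3}, intercept always included), winner by adjusted R² (AIC is
   config-selectable). Ties within 1e−9 go to fewer terms, then lower
   maximum power. Candidates with `n < terms + 2` or rank-deficient
   designs are excluded.
2. **SD model.** Default `binned_by_week`: residuals are grouped by
   rounded predictor (1-week bins for GA, 5-mm bins for BPD/FL — BPD spans
   ≈42–95 mm and FL ≈28–76 mm over 18–40 weeks, so 5-mm bins give ≥ 10
   usable bins), each bin's sample SD is regressed linearly on the bin
   center, weighted by bin count because late-gestation bins are sparse.
   The alternative `absolute_residual` regresses |residual| on `x` and
   scales by √(π/2), the half-normal factor converting a Gaussian mean
   absolute deviation into an SD; it is smoother but less literal about
   treating "the SD" as the observable. The fitted σ(x) must be positive
   over the data range or the fit is rejected.
3. **Z-scores.** Every training observation is standardised with the two
   fitted curves; these scores feed the diagnostics.

Binned SD treats the grouped SD as the dependent variable, which is the
natural reading of step 2 of the classical procedure; whether to weight
the regression is an open choice and we weight by bin count. No outlier
trimming is applied.

## The published registry and sanitization

All 9 mean and 9 SD models are shipped exactly as printed
(`published_registry("as_printed")`). Three entries cannot be used as
printed:

* **Dmin~GA mean** has two linear terms and is negative over the whole
  range — a transcription corruption of unknown intended form. The
  sanitized model uses the internal identity Dmin = Dmax/(1 + DD) applied
  to the published Dmax~GA and DD~GA means, projected onto a cubic on a
  dense grid (projection error < 7e−3 mm ≈ 2% of the Dmin SD; cubic
  matches the degree family of the printed models).
* **DD~GA SD** as printed (0.140 − 0.255×10⁻³·GA) is positive but
  inconsistent by a factor ~1.7 with the SD its own worked z-score example
  implies at 24 weeks (≈ 0.08); a single decimal shift of the slope
  (−2.55×10⁻³) reproduces the example and matches the BPD/FL DD SD models
  in magnitude.
* **DD~BPD SD** as printed goes negative above BPD ≈ 16 mm; the analogous
  decimal correction (−8.040×10⁻⁴) keeps it positive across the range.

The DD~GA *mean* intercept is printed as 0.98 in the coefficient table
and −0.98 in the worked example; we follow the table (the −0.98 form is
negative everywhere, which is impossible for a squared-positive ratio).
Note that neither form reproduces the worked example's printed mean of
0.344 at 24 weeks (the table form gives 0.322); the discrepancy is left
as published rather than silently reconciled. Sanitized models carry
`provenance="published_sanitized"`; sanitized is the scoring default.

Predictor ranges (GA 18–40 w; BPD 42–95 mm; FL 28–76 mm) are the spans
the biometry growth maps produce over the gestational window; out-of-range
scoring warns and flags `extrapolated` rather than erroring, because a
clinical calculator must still return a number.

## Diagnostics

* **P-P plot**: empirical CDF at Hazen positions (i − 0.5)/n (Weibull
  i/(n+1) selectable; they differ by O(1/n)) against the standard- or
  fitted-normal CDF; the summary statistic is the maximum vertical gap.
* **Shapiro–Wilk** as the formal companion to the visual check.
* **Coverage** at both 1.6449 (90% band) and 1.96 (95% band), since both
  conventions circulate; "±2 SD ≈ 10%" statements conflate them, so we
  always report both.
* **Balance**: OLS slope of z on the predictor; a calibrated chart gives
  slope ≈ 0.

## Repeatability (ICC)

Single-measure ICCs from the two-way ANOVA mean squares: ICC(1,1)
(one-way; default for intraobserver replicates), ICC(2,1) absolute
agreement (default for interobserver, where a systematic rater offset
should count against agreement), and ICC(3,1) consistency (offset-blind,
for contrast). Published repeatability tables of this design rarely state
which form was used; values in the 0.93–0.99 range do not disambiguate.
Confidence intervals are McGraw–Wong exact-F bounds (a Satterthwaite
approximation for the ICC(2,1) degrees of freedom). Tables in which every
subject is measured identically short-circuit to ICC = 1 exactly.

## Synthetic cohort generator

Emulates the reference study's design so the whole pipeline is testable
without data access: n = 490 fetuses (default), GA uniform on 18–40 weeks
(an `empirical_skewed` option thins the <20 w and >38 w tails to under 20
cases each, mimicking the stated enrolment sparsity), biometry from linear
growth maps hitting standard anchors (BPD ≈ 47 mm at 20 w, 95 mm at 40 w;
FL ≈ 33 and 76 mm; Gaussian jitter SD 2 mm), and responses drawn from the
sanitized truth charts: DD ~ N(μ_DD(GA), σ_DD(GA)) truncated at 0.01,
Dmax ~ N(μ_Dmax(GA), σ_Dmax(GA)) truncated at 0.5 mm, and
**Dmin = Dmax/(1 + DD)** derived, so the three responses satisfy the
distensibility identity exactly. Deriving Dmin costs control over its
marginal SD (it is induced, ≈ 0.35 mm at 24 w) but guarantees internal
consistency and sidesteps the corrupt printed Dmin mean.

Truncation events are resampled and their fraction logged in
`CohortResult`. With the sanitized truth models the DD floor clips ~4–7%
of draws near 40 weeks (μ_DD → 0.067 while σ_DD → 0.038), ≈ 0.3% of all
draws overall; this mildly right-biases late-gestation DD and makes the
DD z-scores detectably non-Gaussian to Shapiro–Wilk at n = 490 in ~10% of
cohorts. Dmax is effectively untruncated. Consequently passing tests
demonstrate calibration under Gaussian-with-floor sampling, not under
real ultrasound error structure (digit preference, operator drift,
selection at referral) — none of which the generator emulates.

Repeatability tables draw subject true values from the cohort model at
random GA and add N(0, 0.05 mm) per-measurement noise (interobserver
optionally adds a constant rater offset), giving ICCs in the 0.93+ range
of the published repeatability results.

## Numerical choices and problem sizes

* Polynomials are evaluated by exact term summation in float64; charts
  serialise to JSON with full `repr` precision and round-trip bit-exactly.
  Cohort CSVs serialise numbers at 6 significant digits.
* SD-positivity is validated on a 513-point grid at chart construction
  and again pointwise at prediction (`ChartDomainError`).
* Test problem sizes: single-cohort checks at the study size n = 490;
  parameter-recovery and method-agreement checks at n = 2000–5000 with
  20–200 replicates; the calibration summary averages 50 cohorts of 490.
  These sizes put Monte-Carlo error well inside each asserted tolerance.
* Determinism: all randomness flows through `numpy.random.default_rng`
  seeded from the config or CLI flag; fitting itself is seed-free.

## Known limitations

* The sanitized corrections are editorial judgments (decimal shifts, an
  identity-based reconstruction); the as-printed forms remain available
  and every sanitized model is flagged by provenance.
* The SD model is restricted to a line, which can go non-positive under
  extrapolation; charts therefore carry explicit predictor ranges.
* Adjusted-R² model selection admits a spurious higher-order term whenever
  its |t| > 1, so selected mean models may carry one extra small term;
  this inflates no z-score materially but users wanting parsimony should
  use AIC or fixed term sets.
* ICC confidence intervals assume balanced, complete tables; no missing
  cells are supported.
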