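# Methods

`growthfalter` analyses long-format panels of monthly recumbent-length
measurements on young children (roughly 6–27 months of age) to separate
two mechanisms of linear growth faltering: *chronic* faltering (a child
starts small and stays on a persistently slow trajectory) and *episodic*
faltering (transient multi-month velocity deficits). This note documents
the models, the defaults and why they were chosen, and what the synthetic
cohort generator does and does not emulate.

## Anthropometric indices

Ages are stored in days; "months" always means days / 30.44, the same
constant used to convert velocity to cm/month, so knots, age bins and
velocities share one time scale.

- **LAZ** — length-for-age z-score via the LMS transform against a sex- and
  age-specific reference table of (L, M, S): z = ((x/M)^L − 1)/(L·S) for
  L ≠ 0 and ln(x/M)/S for L = 0, with the triple linearly interpolated in
  age. The transform has an analytic inverse, which the tests use as a
  round-trip oracle (identity to 1e-10).
- **LAD** — length-for-age difference, x − M(age, sex), in cm. Unlike LAZ it
  is not variance-standardized, so it keeps accumulating as absolute
  deficits grow; LAZ and LAD always share sign.
- **Velocity** — (length_t − length_{t−1}) / (age_days_t − age_days_{t−1})
  × 30.44 cm/month between consecutive retained visits; undefined at each
  child's first visit. Velocity × gap telescopes exactly to net length
  change, a property test.
- **Plausibility filter** — two configurable rules, flag-then-filter with
  full logging: |LAZ| > 6 (the conventional fixed-limit flag for
  length-based indices) and a within-child decline since the previous
  retained visit exceeding 1.5 cm (several times any plausible measurement
  error). Flagged records are removed, flagging is iterated to a fixed
  point (removing a record can unmask a new decline), velocities are
  re-derived, and children left with fewer than 20 visits are dropped with
  a count in the report.
- **Attained length** — length at the child's last retained visit, the
  continuous outcome used instead of a binary stunting cut at LAZ < −2.
  Quintiles: children are ranked by attained length (child id as the
  deterministic secondary key) and cut at ranks n/5; tied lengths are then
  assigned the lowest provisional quintile of their tie group, so equal
  values never straddle a boundary and an all-tied cohort is all
  quintile 1. Sizes are equal up to the division remainder plus tie
  adjustments.

## Stage 1: per-child growth curves

Each child's length is regressed on age (months) by OLS. The primary form
is the truncated linear spline

    length = b0 + b1·age + Σ_k c_k (age − ξ_k)+ ,  ξ = 9, 12, 15, 18, 21, 24 mo

with (u)+ = max(u, 0) computed exactly (zero at and below the knot).
Alternative forms for sensitivity/selection: a 4-knot linear spline
(knots evenly spaced over the observed 6–27 mo span: 10.2, 14.4, 18.6,
22.8 — an explicit assumption, configurable), a cubic polynomial, and a
restricted (natural) cubic spline with 5 knots at the {5, 27.5, 50, 72.5,
95}% quantiles of the pooled age distribution (the standard placement;
also an assumption, configurable). Forms are compared by child-averaged
AIC and BIC (Gaussian log-likelihood, parameter count = regression
coefficients); the BIC winner is selected, with the AIC winner reported
alongside.

Extracted per child: the intercept, R² (growth-curve *smoothness*: the
share of length variation explained by age alone), the overall F
statistic, and seven *segment velocities* for blocks 6–8, 9–11, 12–14,
15–17, 18–20, 21–23 and 24–end months. For the 6-knot form the block
slope is the exact composition b1 + Σ_{ξ_k ≤ block start} c_k; for other
forms it is the mean slope of the fitted curve over the block (endpoint
difference / width), with the last block running from the 24-mo knot to
the child's final age.

**Intercept convention.** The default intercept is the raw age-0
extrapolation of the spline, not the value at 6 months. With typical
data (first visit ≈ 6.2 mo, length ≈ 65–66 cm) the raw intercept averages
≈ 58 cm; a `center_age_at=6.0` option re-references the age column so the
intercept reads as fitted length at exactly 6 months, which is the
convention the simulator's latent intercept uses and what the exact
recovery tests fit with.

Numerical details: fits use `numpy.linalg.lstsq` with an explicit rank
check; a rank-deficient design (e.g. no observations beyond a knot)
raises an error naming the child, and cohort fitting collects failures
rather than silently dropping children. On noiseless data generated in
the spline basis, coefficients are recovered to 1e-8 and R² = 1
(acceptance property); coefficients agree with an independent dense
normal-equation solve to 1e-9.

## Stage 2: attained length on extracted parameters

A nested sequence of nine child-level OLS models of attained length:
Model 1 on R² alone; Model 2 adds the intercept (initial length); Models
3–9 add the seven segment velocities in age order. R² is multiplied by
100 inside the fitter so its coefficient reads "cm per 0.01 of R²" (a
raw-scale flag exists). Confidence intervals are large-sample normal
(± 1.96 SE) with homoskedastic OLS standard errors — the estimator is
plain OLS throughout, no robust covariance. Model R² is non-decreasing
along the sequence because the models are nested.

An exact algebraic identity anchors the full model: if attained length is
set to each child's fitted endpoint at 28 months (6-mo-centered
parameters), the regression returns coefficient 1 on initial length and
each velocity's block width in months (3 for interior blocks, 4 for
24–28), with model R² = 1. Block widths are computed from knot spacing
and the endpoint age, not hard-coded.

Descriptive tables group children by attained-length quintile (optionally
arm × quintile): mean ± SD with one-way ANOVA for continuous variables,
chi-square for categorical, and pairwise t-tests Bonferroni-corrected by
C(groups, 2). LAZ distributions by quintile at 6/12/18/24 months
(records within ±0.5 mo) are summarized as Gaussian kernel densities
(Scott bandwidth) on a fixed z-grid [−6, 6], exported as tables; each
curve integrates to 1 within 1e-3.

## Slow-growth episodes

A child-month is *slow* when its velocity is strictly below the chosen
centile of velocities among observations in the same age bin (nearest
integer month at the later endpoint; bins with fewer than 30 observations
merged into their nearest neighbour, logged). Centile values use linear
rank interpolation; ties at the cutoff are not flagged (strict `<`), so a
bin of identical velocities flags nothing and cutoff 0 flags nothing.

The working centile is the smallest candidate (1–50) at which strictly
more than 95% of children have at least one slow month. Coverage is
monotone in the centile, so the feasibility set is an interval and the
choice is well defined; the full coverage-vs-centile curve is reported.
Which centile this selects depends on the ratio of measurement error to
true velocity heterogeneity, so the synthetic default cohort typically
selects a centile in the low-to-mid 20s rather than any particular
real-data value.

Episodes are maximal runs of consecutive slow months; a between-visit gap
exceeding 45 days (1.5 × the nominal monthly interval, configurable)
breaks a run, as does the first visit of a child (no velocity). The run
encoder is verified against brute-force enumeration on 10,000 random
flag/gap sequences.

Sensitivity definition: negative residuals from a *pooled* OLS of length
on the 6-knot age basis plus each child's first retained length. Pooled
rather than per-child, because per-child residuals conditional on the
child's own data sum to zero per child and would mechanically flag about
half of every child's months regardless of faltering; the per-child
variant is still available behind a flag for exactly that comparison.

Per-child summaries (any ≥2-consecutive spell; total slow months; longest
run; age block of first onset among 7–8, 9–11, …, 24–28, or never) feed
child-level OLS regressions of attained length, one exposure at a time,
each adjusted for study arm (first label as reference), total reported
illness episodes, and length at first measurement; the onset model uses
age-block indicators with "never" as reference. Estimator calibration is
checked against a summary-level generator that draws attained length from
the same regression with a known coefficient: the planted effect is
recovered within Monte-Carlo error, and with a zero effect the 95% CI
covers zero at the nominal rate. Because the centile definition is
relative, detected-exposure coefficients on the full simulated cohort
absorb chronic trajectory differences and are therefore larger in
magnitude than the injected per-episode deficit — this is a property of
the definition, not an estimator bias.

## Synthetic cohort generator

The generator's defaults emulate the study design the analysis assumes:
~6.16 ± 0.58 months at enrollment, 22 scheduled visits at 30.44 ± 2 day
intervals with 3% missed (≈ 21.4 realized observations per child through
~27 months), segment velocity means (1.27, 1.02, 0.94, 0.92, 0.88, 0.82,
0.70) cm/month across the seven blocks, and measurement error of 0.2 cm
(the common field retake tolerance) averaged over duplicate measurements
(halving its variance). Latent velocity SDs (0.30, 0.25, 0.22, 0.22,
0.21, 0.21, 0.25) were set slightly below fitted-parameter dispersions
typical of such cohorts, since fitted values add estimation noise.

- **Chronic faltering**: a child's intercept z-score and a shared frailty
  are correlated (default 0.6); the frailty loads (default 0.7) on all
  seven segment velocities, so small children also grow slowly everywhere.
- **Episodic faltering**: spells start at a visit with probability 0.08
  when none is active, last Geometric(0.6) visits (mean ≈ 1.7), and
  subtract 0.7 cm/month from growth into each affected visit; lost growth
  is never recovered. Illness reports are Bernoulli-linked to spells
  (0.5 in-spell vs 0.05 background).
- **Latent shape**: trajectories are generated directly in the 6-knot
  spline basis so stage-1 correctness has an exact oracle; a `smooth`
  option interpolates velocity continuously between block midpoints to
  produce curves *outside* the fitted family for misspecification
  experiments.
- **Reference table**: generated, not copied — a median curve integrating
  an exponentially decaying velocity (birth ≈ 50 cm, M(6 mo) in the
  mid-60s, M(24 mo) in the mid-80s), S rising mildly with age, L ≡ 1,
  small seeded parameter jitter, boys slightly longer. Real WHO-style
  LMS tables in the same `sex, age_days, L, M, S` CSV layout are accepted
  everywhere a reference is used.

What the generator does **not** emulate: seasonality, age-dependent
measurement error, informative missingness, within-child serial
correlation of error, weight-based indices, or the third-measurement
field rule. Passing tests therefore demonstrate estimator correctness
and pipeline integrity under the stated data-generating process, not
robustness to every feature of field data.

Determinism: every child draws from its own `SeedSequence(seed,
spawn_key)` substream; identical configuration reproduces panels bit for
bit, and the pipeline manifest records the seed and every decision
parameter (knots, limits, gaps, bin merges, selected form and centile).

## Problem sizes

The test suite exercises cohorts of 30–800 children; the acceptance
script uses 1,000 children for the headline pipeline quantities and
2,000 (20 seeds) / 500 (500 replicates) for effect-recovery and type-I
calibration — sizes at which Monte-Carlo error is small relative to the
tolerances being checked while a full run stays in the minutes range on
one CPU.

## Known limitations

- The plausibility filter is a deliberate, configurable stand-in for
  study-specific cleaning rules; retention rates are not comparable
  across rule sets.
- The episode regressions are child-level; velocity observations within
  children are serially dependent and the centile exposure is relative,
  so coefficients are associations under this cohort's structure, not
  causal per-insult effects.
- The 4-knot and restricted-cubic knot placements are assumptions and
  should be set explicitly when comparing against any external analysis.
- Second-stage CIs ignore that stage-1 parameters are estimates
  (no errors-in-variables correction), matching standard two-stage
  extracted-parameter practice.
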