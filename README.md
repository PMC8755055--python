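# growthfalter

Analysis toolkit for **linear growth faltering in longitudinal child
anthropometry**: given monthly recumbent-length panels on children
roughly 6–27 months old, it separates *chronic* faltering (children who
start small and stay on persistently slow trajectories) from *episodic*
faltering (transient multi-month velocity insults), and quantifies how
both relate to attained length at the end of follow-up.

It is written for biostatisticians and epidemiologists working with
high-frequency growth cohorts who want a tested, reproducible
implementation of:

1. **Anthropometric indices** — length-for-age z-scores via the LMS
   transform (z = ((x/M)^L − 1)/(L·S), with analytic inverse),
   length-for-age differences in cm, monthly velocity
   (Δlength/Δdays × 30.44), a configurable plausibility filter, and
   attained-length quintiles.
2. **Stage-1 growth curves** — per-child OLS of length on age in a
   truncated linear spline basis, length = β₀ + β₁·age + Σₖ bₖ(age − ξₖ)₊
   with knots ξ = 9, 12, 15, 18, 21, 24 mo (alternative forms: 4-knot
   spline, cubic polynomial, restricted cubic spline; compared by
   child-averaged AIC/BIC). Extracts the intercept (initial length), R²
   (growth-curve smoothness), F, and seven age-block segment velocities.
3. **Stage-2 attained-length models** — a nested OLS sequence of attained
   length on R², initial length, then each block velocity in turn (R²
   scaled so coefficients read cm per 0.01), with quintile descriptive
   tables (ANOVA/Bonferroni) and tabular LAZ kernel densities.
4. **Slow-growth episodes** — a child-month is slow when its velocity
   falls below the age-specific cohort centile; the cutoff is the lowest
   centile at which >95% of children have ≥1 slow month; maximal
   consecutive runs form episodes, summarized and regressed (adjusted
   for arm, illness, initial length) against attained length. A pooled
   negative-residual definition is available as a sensitivity.
5. **Synthetic cohort simulator** — seeded generator of the whole data
   structure (reference table included) with chronic and episodic
   faltering injected and latent truth returned, so every estimator has
   an exact oracle.

## Worked example

```python
from growthfalter import (SimulationConfig, generate_reference,
                          simulate_cohort, filter_implausible,
                          fit_cohort_curves, extract_stage1_table,
                          attained_length, fit_model_sequence)

reference = generate_reference(seed=4)
panel, _ = simulate_cohort(SimulationConfig(n_children=400, seed=4), reference)
derived, _ = filter_implausible(panel, reference)
stage1 = extract_stage1_table(fit_cohort_curves(derived)[0])
sequence = fit_model_sequence(stage1, attained_length(derived))
for fit in sequence:
    print(fit.model_id, round(fit.r_squared, 3))
```

Running `python examples/04_attained_length_models.py` (the same
computation, with printing) gives:

```
model  R^2_model  coef(R^2 per 0.01)  coef(initial length)
    1      0.322              28.834                   nan
    2      0.372              28.675                 0.492
    3      0.839              13.821                 1.442
    ...
    9      0.993              -0.070                 0.999

full-model velocity coefficients (cm per 1 cm/mo):
  v_9_11: 2.995 (2.810, 3.180)
  ...
```

Reading: smoothness (R²) alone explains 32% of attained-length variance,
but once initial length and all seven block velocities enter, model R²
reaches 0.993 and the smoothness coefficient collapses toward zero — the
velocities carry the signal. Each velocity coefficient approaches the
months spent in its block (≈3 for interior blocks), because growing
1 cm/month faster for a 3-month block adds ≈3 cm to the endpoint.

The other scripts in `examples/` walk the remaining capabilities:
simulation structure, LAZ/LAD/velocity derivation, functional-form
comparison, episode detection and its regressions, and the one-call
pipeline. A thin CLI wraps the pipeline for shell use:

```bash
growthfalter simulate --n 500 --seed 42 --out panel.csv --reference-out ref.csv
growthfalter all --seed 7 --out-dir run_out          # full bundle + manifest
growthfalter validate panel.csv                       # schema/consistency checks
```

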