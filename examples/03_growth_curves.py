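"""Per-child spline growth curves and functional-form comparison.

Fits every child's length-on-age regression in four candidate forms,
compares child-averaged AIC/BIC, and summarizes the extracted parameters
(intercept, smoothness R^2, segment velocities) under the selected form.
"""

from growthfalter import (SimulationConfig, generate_reference,
                          simulate_cohort, compare_forms, fit_cohort_curves,
                          extract_stage1_table, VELOCITY_COLUMNS)

reference = generate_reference(seed=3)
panel, _ = simulate_cohort(SimulationConfig(n_children=200, seed=3),
                           reference)

comparison = compare_forms(panel)
print(comparison.table.to_string(index=False,
                                 float_format=lambda v: f"{v:.1f}"))
print(f"selected by BIC: {comparison.selected_form} "
      f"(AIC winner: {comparison.aic_selected_form})")

fits, failures = fit_cohort_curves(panel, comparison.selected_form)
stage1 = extract_stage1_table(fits)
print(f"\nfitted {len(fits)} children ({len(failures)} failures)")
print(f"intercept: {stage1['intercept'].mean():.2f} "
      f"+/- {stage1['intercept'].std():.2f} cm (age-0 extrapolation)")
print(f"R^2: {stage1['r_squared'].mean():.4f} "
      f"+/- {stage1['r_squared'].std():.4f}")
for col in VELOCITY_COLUMNS:
    print(f"velocity {col[2:].replace('_', '-'):>6} mo: "
          f"{stage1[col].mean():.2f} +/- {stage1[col].std():.2f} cm/mo")

# The 6-knot linear spline wins BIC because the simulator's latent
# trajectories live in exactly that basis; velocities decline with age as
# configured. R^2 near 1 = smooth growth; children with episodes sit lower.
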