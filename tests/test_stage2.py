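import numpy as np
import pandas as pd
import pytest

from growthfalter import (attained_length, extract_stage1_table,
                          fit_cohort_curves, fit_model_sequence,
                          quintile_descriptives, laz_density_summary,
                          MODEL_TERMS, VELOCITY_COLUMNS)
from growthfalter.errors import SingularModelError
from growthfalter.simulate import SimulationConfig, simulate_cohort
from growthfalter.stage2 import model_sequence_table


def identity_attained(stage1):
    """Exact fitted endpoint at 28 mo from 6-mo-centered parameters:
    intercept + 3 mo of each interior block velocity + 4 mo of the last."""
    widths = np.array([3.0] * 6 + [4.0])
    v = stage1[list(VELOCITY_COLUMNS)].to_numpy()
    return stage1["intercept"].to_numpy() + v @ widths


@pytest.fixture(scope="module")
def stage1_and_attained(noisy_cohort):
    panel, _ = noisy_cohort
    fits, _ = fit_cohort_curves(panel, center_age_at=6.0)
    stage1 = extract_stage1_table(fits)
    attained = attained_length(panel)
    return stage1, attained


class TestModelSequence:
    def test_nested_terms_grow_one_velocity_at_a_time(self):
        assert MODEL_TERMS[0] == ["r_squared"]
        assert MODEL_TERMS[1] == ["r_squared", "intercept"]
        for m in range(2, 9):
            assert MODEL_TERMS[m][:-1] == MODEL_TERMS[m - 1]
            assert MODEL_TERMS[m][-1] == VELOCITY_COLUMNS[m - 2]

    def test_identity_cohort_recovers_block_widths(self, stage1_and_attained):
        stage1, attained = stage1_and_attained
        att = attained.copy()
        ident = pd.DataFrame({"child_id": stage1["child_id"],
                              "attained_length_cm": identity_attained(stage1)})
        att = att.drop(columns="attained_length_cm").merge(ident,
                                                           on="child_id")
        fits = fit_model_sequence(stage1, att)
        m9 = fits[-1]
        assert m9.r_squared == pytest.approx(1.0, abs=1e-9)
        assert m9.params["intercept"] == pytest.approx(1.0, abs=1e-6)
        for col in VELOCITY_COLUMNS[:-1]:
            assert m9.params[col] == pytest.approx(3.0, abs=1e-6)
        assert m9.params["v_24_28"] == pytest.approx(4.0, abs=1e-6)
        assert m9.params["r_squared"] == pytest.approx(0.0, abs=1e-6)

    def test_model_r_squared_never_decreases(self, stage1_and_attained):
        stage1, attained = stage1_and_attained
        fits = fit_model_sequence(stage1, attained)
        r2 = [f.r_squared for f in fits]
        assert all(b >= a - 1e-12 for a, b in zip(r2, r2[1:]))

    def test_r2_rescaling_reads_per_001_units(self, stage1_and_attained):
        stage1, attained = stage1_and_attained
        scaled = fit_model_sequence(stage1, attained, rescale_r2=True)
        raw = fit_model_sequence(stage1, attained, rescale_r2=False)
        assert scaled[0].params["r_squared"] * 100 == pytest.approx(
            raw[0].params["r_squared"], rel=1e-9)

    def test_ols_matches_normal_equations(self, stage1_and_attained):
        stage1, attained = stage1_and_attained
        sub = stage1.iloc[:50]
        att = attained[attained["child_id"].isin(sub["child_id"])]
        fits = fit_model_sequence(sub, att)
        df = sub.merge(att[["child_id", "attained_length_cm"]], on="child_id")
        for m, fit in enumerate(fits, start=1):
            X = np.column_stack(
                [np.ones(len(df))]
                + [(df[t] * 100 if t == "r_squared" else df[t]).to_numpy()
                   for t in fit.terms])
            y = df["attained_length_cm"].to_numpy()
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            got = np.array([fit.params[t] for t in fit.terms])
            np.testing.assert_allclose(got, beta[1:], atol=1e-9)

    def test_collinear_predictors_raise_naming_model(self,
                                                     stage1_and_attained):
        stage1, attained = stage1_and_attained
        broken = stage1.copy()
        broken["r_squared"] = 0.995  # constant duplicates the intercept
        with pytest.raises(SingularModelError, match="Model 1"):
            fit_model_sequence(broken, attained)

    def test_wide_table_mirrors_long_output(self, stage1_and_attained):
        stage1, attained = stage1_and_attained
        fits = fit_model_sequence(stage1, attained)
        wide, long, meta = model_sequence_table(fits)
        assert wide.shape == (9, 9)
        assert np.isnan(wide.loc["v_24_28", 1])
        assert wide.loc["v_24_28", 9] == pytest.approx(
            fits[-1].params["v_24_28"])
        assert meta.loc[9, "n"] == fits[-1].n


class TestDescriptives:
    def test_identical_groups_give_p_near_one(self):
        base = pd.DataFrame({"x": np.tile(np.arange(10.0), 2),
                             "g": np.repeat([1, 2], 10)})
        summary, _ = quintile_descriptives(base, ["x"], group="g")
        assert (summary["pvalue"] >= 0.99).all()

    def test_planted_shift_is_detected_after_bonferroni(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "x": np.concatenate([rng.normal(0, 1, 100),
                                 rng.normal(5, 1, 100)]),
            "g": np.repeat([1, 2], 100)})
        summary, pairs = quintile_descriptives(df, ["x"], group="g")
        assert (summary["pvalue"] < 0.001).all()
        assert (pairs["p_bonferroni"] < 0.001).all()

    def test_small_group_excluded_with_warning(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 9.0],
                           "g": [1, 1, 1, 2]})
        with pytest.warns(UserWarning, match="n < 2"):
            summary, _ = quintile_descriptives(df, ["x"], group="g")
        assert set(summary["group"]) == {1}

    def test_categorical_variable_uses_chi_square(self, derived_cohort):
        att = attained_length(derived_cohort)
        first = derived_cohort.groupby("child_id").first().reset_index()
        data = att.merge(first[["child_id", "sex"]], on="child_id")
        summary, _ = quintile_descriptives(
            data, ["sex"], group="quintile", categorical=("sex",))
        assert (summary["test"] == "chi2").all()


class TestDensities:
    def test_curves_integrate_to_one(self, derived_cohort):
        att = attained_length(derived_cohort)
        dens = laz_density_summary(derived_cohort, att, ages_mo=(12, 18))
        for (q, age), grp in dens.groupby(["quintile", "age_mo"]):
            integral = np.trapezoid(grp["density"], grp["z"])
            assert integral == pytest.approx(1.0, abs=1e-3)

    def test_uniform_length_shift_translates_densities(self, noisy_cohort,
                                                       reference):
        from growthfalter import filter_implausible
        panel, _ = noisy_cohort
        base, _ = filter_implausible(panel, reference)
        att = attained_length(base)
        dens0 = laz_density_summary(base, att, ages_mo=(12,))

        # shift all lengths down; with L=1 the z-shift is delta/(S*M)
        shifted = panel.copy()
        shifted["length_cm"] -= 1.0
        sh, _ = filter_implausible(shifted, reference)
        att_s = attained_length(sh)
        dens1 = laz_density_summary(sh, att_s, ages_mo=(12,))

        sub = base[np.abs(base["age_days"] / 30.44 - 12) <= 0.5]
        dz = (sub["laz"].mean()
              - sh[np.abs(sh["age_days"] / 30.44 - 12) <= 0.5]["laz"].mean())
        for q in dens0["quintile"].unique():
            g0 = dens0[dens0["quintile"] == q]
            g1 = dens1[dens1["quintile"] == q]
            mode0 = g0.loc[g0["density"].idxmax(), "z"]
            mode1 = g1.loc[g1["density"].idxmax(), "z"]
            assert mode0 - mode1 == pytest.approx(dz, abs=0.15)

    def test_empty_age_window_warns_and_omits(self, derived_cohort):
        att = attained_length(derived_cohort)
        with pytest.warns(UserWarning):
            dens = laz_density_summary(derived_cohort, att, ages_mo=(40,))
        assert len(dens) == 0
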