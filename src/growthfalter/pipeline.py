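"""End-to-end orchestration: simulate/load -> derive -> fit -> report.

:func:`run_pipeline` sequences the full analysis behind a single
:class:`RunConfig` (loadable from YAML), writes every stage output as CSV
plus a machine-readable ``manifest.json`` recording the seed and every
decision parameter, and is bit-reproducible under a fixed config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, PanelDataError
from .reference import GrowthReference, generate_reference
from .simulate import SimulationConfig, simulate_cohort, latents_to_frame
from .indices import (PANEL_COLUMNS, filter_implausible, attained_length)
from .curves import (FORMS, fit_cohort_curves, extract_stage1_table,
                     compare_forms, VELOCITY_COLUMNS)
from .stage2 import (fit_model_sequence, model_sequence_table,
                     quintile_descriptives, laz_density_summary)
from .episodes import (velocity_centile_flags, select_threshold, detect_runs,
                       residual_flags, summarize_episodes,
                       episode_quintile_summary, build_child_covariates,
                       fit_episode_regressions, episode_regression_table)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration for a full pipeline run.

    Exactly one of ``panel_path`` (with ``reference_path``) or
    ``simulation`` must be provided.
    """

    out_dir: str = "growthfalter_run"
    seed: int = 0
    panel_path: str | None = None
    reference_path: str | None = None
    simulation: SimulationConfig | None = None
    # plausibility filter
    z_limit: float = 6.0
    decline_limit_cm: float = 1.5
    min_visits: int = 20
    # stage 1
    form: str = "linear_spline_6"
    center_age_at: float = 0.0
    compare_all_forms: bool = True
    # episodes
    coverage: float = 0.95
    fixed_centile: float | None = None  # skip threshold search if set
    max_gap_days: float = 45.0
    min_bin_n: int = 30
    # densities
    density_ages_mo: tuple = (6, 12, 18, 24)

    def validate(self) -> None:
        has_paths = self.panel_path is not None
        has_sim = self.simulation is not None
        if has_paths == has_sim:
            raise ConfigError("panel_path/simulation",
                              "provide exactly one of an input panel path "
                              "or a simulation block")
        if has_paths and not Path(self.panel_path).exists():
            raise ConfigError("panel_path",
                              f"no such file: {self.panel_path}")
        if has_paths:
            if self.reference_path is None:
                raise ConfigError("reference_path",
                                  "required when panel_path is given")
            if not Path(self.reference_path).exists():
                raise ConfigError("reference_path",
                                  f"no such file: {self.reference_path}")
        if self.form not in FORMS:
            raise ConfigError("form", f"must be one of {FORMS}")
        if not 0.0 <= self.coverage < 1.0:
            raise ConfigError("coverage", "must lie in [0, 1)")
        if has_sim:
            self.simulation.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        d["density_ages_mo"] = list(self.density_ages_mo)
        return d


@dataclass
class ValidationReport:
    path: str
    n_rows: int
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_panel(source) -> ValidationReport:
    """Schema and consistency checks for a long-format panel CSV.

    Checks required columns, within-child strict age monotonicity (in file
    order), and duplicate (child_id, visit_index) keys; every violation is
    reported with the offending 0-based data row number.
    """
    if isinstance(source, pd.DataFrame):
        df, name = source.copy(), "<frame>"
    else:
        df, name = pd.read_csv(source), str(source)
    report = ValidationReport(name, len(df))
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        report.violations.append({"row": None, "kind": "schema",
                                  "detail": f"missing columns {missing}"})
        return report
    df = df.reset_index(drop=True)
    dup = df.duplicated(["child_id", "visit_index"], keep="first")
    for row in df.index[dup]:
        report.violations.append({
            "row": int(row), "kind": "duplicate_key",
            "detail": f"duplicate child-visit "
                      f"({df.at[row, 'child_id']}, "
                      f"{df.at[row, 'visit_index']})"})
    prev_age = df.groupby("child_id")["age_days"].shift()
    bad = prev_age.notna() & (df["age_days"] <= prev_age)
    for row in df.index[bad]:
        report.violations.append({
            "row": int(row), "kind": "age_not_increasing",
            "detail": f"age_days not strictly increasing for child "
                      f"{df.at[row, 'child_id']}"})
    if (df["length_cm"] <= 0).any():
        for row in df.index[df["length_cm"] <= 0]:
            report.violations.append({"row": int(row), "kind": "domain",
                                      "detail": "non-positive length_cm"})
    return report


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Stages: obtain panel (simulate or read) -> plausibility filter and
    derived indices -> per-child spline fits (+ optional functional-form
    comparison) -> nested attained-length models -> slow-growth threshold
    selection, episode detection and regressions -> LAZ density curves.
    Returns the manifest dict (also written as ``manifest.json``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulation is not None:
        reference = generate_reference(seed=config.seed)
        panel, latents = simulate_cohort(config.simulation, reference)
        reference.to_csv(out / "reference.csv")
        _write(panel, out / "panel.csv")
        _write(latents_to_frame(latents), out / "latent_truth.csv")
    else:
        reference = GrowthReference.from_csv(config.reference_path)
        panel = pd.read_csv(config.panel_path)
        report = validate_panel(panel)
        if not report.ok:
            raise PanelDataError(
                f"input panel failed validation with "
                f"{len(report.violations)} violation(s); first: "
                f"{report.violations[0]}")

    derived, filt = filter_implausible(
        panel, reference, config.z_limit, config.decline_limit_cm,
        config.min_visits)
    _write(derived, out / "derived_panel.csv")

    attained = attained_length(derived)
    _write(attained, out / "attained_length.csv")

    form_used = config.form
    comparison = None
    if config.compare_all_forms:
        comparison = compare_forms(derived, center_age_at=config.center_age_at)
        _write(comparison.table, out / "form_comparison.csv")
        form_used = comparison.selected_form
    fits, failures = fit_cohort_curves(
        derived, form_used, center_age_at=config.center_age_at)
    stage1 = extract_stage1_table(fits)
    _write(stage1, out / "stage1_parameters.csv")

    seq = fit_model_sequence(stage1, attained)
    wide, long, meta = model_sequence_table(seq)
    _write(long, out / "model_sequence.csv")
    wide.to_csv(out / "model_sequence_wide.csv")
    meta.to_csv(out / "model_sequence_meta.csv")

    desc_vars = ["attained_length_cm"]
    desc_input = attained.merge(
        stage1[["child_id", "intercept", "r_squared"]
               + list(VELOCITY_COLUMNS)], on="child_id")
    summary, pairs = quintile_descriptives(
        desc_input, ["attained_length_cm", "intercept", "r_squared",
                     "v_6_8", "v_9_11"], group="quintile")
    _write(summary, out / "quintile_descriptives.csv")
    _write(pairs, out / "quintile_pairwise.csv")

    if config.fixed_centile is not None:
        centile = config.fixed_centile
        curve = pd.DataFrame({"centile": [centile], "coverage": [np.nan]})
    else:
        centile, curve = select_threshold(
            derived, config.coverage, min_bin_n=config.min_bin_n)
    _write(curve, out / "threshold_curve.csv")
    flags = velocity_centile_flags(derived, centile, config.min_bin_n)
    eps = detect_runs(derived, flags, config.max_gap_days)
    ep_df = pd.DataFrame([{"child_id": e.child_id,
                           "threshold_kind": e.threshold_kind,
                           "start_visit_index": e.start_visit_index,
                           "start_age_mo": e.start_age_mo,
                           "run_length": e.run_length} for e in eps])
    _write(ep_df, out / "episodes.csv")
    summaries = summarize_episodes(eps, derived)
    _write(summaries, out / "episode_summaries.csv")
    _write(episode_quintile_summary(summaries, attained, flags, derived),
           out / "episode_quintile_summary.csv")

    cov = build_child_covariates(derived, attained)
    reg = fit_episode_regressions(summaries, cov)
    _write(episode_regression_table(reg), out / "episode_regressions.csv")

    res_flags = residual_flags(derived)
    res_eps = detect_runs(derived, res_flags, config.max_gap_days,
                          threshold_kind="residual")
    res_sum = summarize_episodes(res_eps, derived)
    res_reg = fit_episode_regressions(res_sum, cov)
    _write(episode_regression_table(res_reg),
           out / "episode_regressions_residual.csv")

    dens = laz_density_summary(derived, attained,
                               ages_mo=config.density_ages_mo)
    _write(dens, out / "laz_density_curves.csv")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "n_records_in": int(len(panel)),
        "n_records_retained": int(len(derived)),
        "n_children_retained": int(derived["child_id"].nunique()),
        "filter": {"n_flagged": filt.n_records_flagged,
                   "n_children_dropped": filt.n_children_dropped,
                   "flag_counts": filt.flag_counts},
        "stage1_form": form_used,
        "stage1_failures": failures,
        "form_comparison": (comparison.table.to_dict("records")
                            if comparison is not None else None),
        "selected_centile": float(centile),
        "model_r_squared": {f.model_id: f.r_squared for f in seq},
        "n_episodes": int(len(eps)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
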