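"""Synthetic monthly child-length cohort generator.

Emulates the longitudinal structure the downstream analysis assumes:
children enrolled near 6 months of age and measured roughly monthly to
~27 months, with two distinct faltering mechanisms —

* **chronic faltering**: child-specific piecewise-linear latent
  trajectories whose intercept (length at 6 mo) and segment velocities are
  positively correlated through a shared frailty, so short children start
  smaller *and* grow more slowly along the whole trajectory;
* **episodic faltering**: transient 1–3-visit velocity insults that
  permanently subtract growth during the spell.

Observed length adds Gaussian measurement error (optionally averaged over
duplicate measurements, as in field protocols). Latent truth is returned
alongside the panel so estimator correctness has an exact oracle.

The latent trajectories are generated directly in the truncated-linear-
spline basis (slope breaks at 9, 12, 15, 18, 21, 24 mo) so that a
noiseless, episode-free cohort is *exactly* representable by the stage-1
growth-curve model; a ``latent_shape="smooth"`` option substitutes a
smooth velocity curve for misspecification experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError
from .reference import GrowthReference
from .units import DAYS_PER_MONTH

#: Age-block boundaries (months): blocks 6-8, 9-11, ..., 21-23, 24-end.
BLOCK_STARTS_MO = (6.0, 9.0, 12.0, 15.0, 18.0, 21.0, 24.0)
N_BLOCKS = len(BLOCK_STARTS_MO)

DEFAULT_ARM_LABELS = ("CSB+", "CSWB", "SC+", "RUSF")


@dataclass
class SimulationConfig:
    """All knobs of the cohort simulator, with study-scale defaults.

    Defaults are calibrated to the cohort the analysis is designed for:
    enrollment at 6.16 +/- 0.58 mo, ~22 scheduled monthly visits with a few
    percent missed (~21.5 realized observations per child), segment
    velocity means declining from ~1.27 cm/mo (6-8 mo) to ~0.70 cm/mo
    (24+ mo), and 0.2 cm measurement error (the field retake tolerance),
    halved in variance by duplicate measurement.
    """

    n_children: int = 1000
    seed: int = 0
    enrollment_age_mean_mo: float = 6.16
    enrollment_age_sd_mo: float = 0.58
    n_visits_target: int = 22
    visit_interval_days_mean: float = 30.44
    visit_interval_jitter_sd_days: float = 2.0
    missing_visit_prob: float = 0.03
    latent_intercept_mean_cm: float | None = None  # None -> reference M(6 mo) - 1.4
    latent_intercept_sd_cm: float = 2.4
    segment_velocity_means_cm_mo: tuple = (1.27, 1.02, 0.94, 0.92, 0.88, 0.82, 0.70)
    segment_velocity_sd_cm_mo: tuple = (0.30, 0.25, 0.22, 0.22, 0.21, 0.21, 0.25)
    intercept_velocity_corr: float = 0.6
    velocity_frailty_loading: float = 0.7
    episode_rate_per_visit: float = 0.08
    episode_duration_geometric_p: float = 0.6
    episode_velocity_deficit_cm_mo: float = 0.7
    measurement_error_sd_cm: float = 0.2
    duplicate_measure: bool = True
    arm_labels: tuple = DEFAULT_ARM_LABELS
    illness_link_prob: float = 0.5
    illness_background_prob: float = 0.05
    latent_shape: str = "piecewise"  # or "smooth"
    start_date: str = "2014-08-01"
    enrollment_window_days: int = 300

    def validate(self) -> None:
        """Raise :class:`ConfigError` naming the first offending field."""
        if self.n_children < 1:
            raise ConfigError("n_children", "must be >= 1")
        for name in ("missing_visit_prob", "episode_rate_per_visit",
                     "illness_link_prob", "illness_background_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(name, "probability must lie in [0, 1]")
        if not 0.0 < self.episode_duration_geometric_p <= 1.0:
            raise ConfigError("episode_duration_geometric_p",
                              "must lie in (0, 1]")
        for name in ("enrollment_age_sd_mo", "visit_interval_jitter_sd_days",
                     "latent_intercept_sd_cm", "measurement_error_sd_cm"):
            if getattr(self, name) < 0:
                raise ConfigError(name, "standard deviation must be >= 0")
        if self.enrollment_age_mean_mo <= 0:
            raise ConfigError("enrollment_age_mean_mo", "must be positive")
        if self.visit_interval_days_mean <= 0:
            raise ConfigError("visit_interval_days_mean", "must be positive")
        if self.n_visits_target < 2:
            raise ConfigError("n_visits_target", "need at least 2 visits")
        if abs(self.intercept_velocity_corr) > 1:
            raise ConfigError("intercept_velocity_corr", "must lie in [-1, 1]")
        if not 0.0 <= self.velocity_frailty_loading <= 1.0:
            raise ConfigError("velocity_frailty_loading", "must lie in [0, 1]")
        if len(self.segment_velocity_means_cm_mo) != N_BLOCKS:
            raise ConfigError("segment_velocity_means_cm_mo",
                              f"need {N_BLOCKS} values (one per age block)")
        if len(self.segment_velocity_sd_cm_mo) != N_BLOCKS:
            raise ConfigError("segment_velocity_sd_cm_mo",
                              f"need {N_BLOCKS} values (one per age block)")
        if any(s < 0 for s in self.segment_velocity_sd_cm_mo):
            raise ConfigError("segment_velocity_sd_cm_mo", "sds must be >= 0")
        if self.episode_velocity_deficit_cm_mo < 0:
            raise ConfigError("episode_velocity_deficit_cm_mo", "must be >= 0")
        if self.latent_shape not in ("piecewise", "smooth"):
            raise ConfigError("latent_shape", "must be 'piecewise' or 'smooth'")
        if len(self.arm_labels) < 1:
            raise ConfigError("arm_labels", "need at least one arm label")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["segment_velocity_means_cm_mo"] = list(self.segment_velocity_means_cm_mo)
        d["segment_velocity_sd_cm_mo"] = list(self.segment_velocity_sd_cm_mo)
        d["arm_labels"] = list(self.arm_labels)
        return d


@dataclass
class LatentChild:
    """Ground truth for one simulated child."""

    child_id: str
    sex: str
    arm: str
    latent_intercept_cm: float          # latent length at exactly 6.0 mo
    latent_segment_velocities: np.ndarray  # cm/mo, one per age block
    episode_spells: list = field(default_factory=list)  # (start_visit_idx, duration)


def _latent_length_piecewise(age_mo, intercept_cm, seg_v):
    """Latent length at age(s), piecewise linear with breaks at block starts."""
    a = np.atleast_1d(np.asarray(age_mo, dtype=float))
    bounds = np.asarray(BLOCK_STARTS_MO)
    out = np.full(a.shape, float(intercept_cm))
    for j in range(N_BLOCKS):
        lo = bounds[j]
        hi = bounds[j + 1] if j + 1 < N_BLOCKS else np.inf
        # signed overlap so ages below 6 mo extrapolate with the first slope
        if j == 0:
            width = np.minimum(a, hi) - lo
        else:
            width = np.clip(np.minimum(a, hi) - lo, 0.0, None)
        out = out + seg_v[j] * width
    return out if np.ndim(age_mo) else float(out[0])


def _latent_length_smooth(age_mo, intercept_cm, seg_v):
    """Smooth variant: velocity interpolated linearly between block midpoints.

    Not representable by the linear-spline fit; used for misspecification
    experiments only.
    """
    mids = np.array([7.5, 10.5, 13.5, 16.5, 19.5, 22.5, 26.0])
    grid = np.arange(4.0, 32.0 + 1e-9, 0.02)
    v = np.interp(grid, mids, seg_v)
    cum = np.concatenate([[0.0], np.cumsum((v[1:] + v[:-1]) / 2.0 * np.diff(grid))])
    at6 = np.interp(6.0, grid, cum)
    a = np.asarray(age_mo, dtype=float)
    return intercept_cm + np.interp(a, grid, cum) - at6


def _draw_spells(rng, n_intervals, rate, geom_p):
    """Non-overlapping episode spells over velocity intervals 1..n_intervals."""
    spells = []
    t = 1
    while t <= n_intervals:
        if rng.random() < rate:
            dur = int(rng.geometric(geom_p))
            dur = min(dur, n_intervals - t + 1)
            spells.append((t, dur))
            t += dur
        else:
            t += 1
    return spells


def simulate_cohort(config: SimulationConfig,
                    reference: GrowthReference | None = None):
    """Simulate a long-format cohort panel plus its latent ground truth.

    Returns ``(panel, latents)`` where ``panel`` is a DataFrame with columns
    ``child_id, sex, arm, visit_index, date, age_days, length_cm,
    illness_reported`` (one row per realized child-visit, ages strictly
    increasing within child) and ``latents`` is a list of
    :class:`LatentChild`.

    Identical ``config`` (including seed) always reproduces the identical
    panel bit for bit; each child draws from its own seeded substream.
    """
    config.validate()

    if config.latent_intercept_mean_cm is not None:
        intercept_mean = config.latent_intercept_mean_cm
    elif reference is not None:
        sexes = reference.sexes
        m6 = np.mean([reference.median(s, 6.0 * DAYS_PER_MONTH) for s in sexes])
        intercept_mean = float(m6) - 1.4
    else:
        intercept_mean = 64.4

    latent_fn = (_latent_length_piecewise if config.latent_shape == "piecewise"
                 else _latent_length_smooth)

    seg_means = np.asarray(config.segment_velocity_means_cm_mo, dtype=float)
    seg_sds = np.asarray(config.segment_velocity_sd_cm_mo, dtype=float)
    rho = config.intercept_velocity_corr
    lam = config.velocity_frailty_loading
    start = pd.Timestamp(config.start_date)

    id_width = max(4, len(str(config.n_children)))
    cohort_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(0,)))

    rows = []
    latents = []
    for i in range(config.n_children):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(1, i)))
        child_id = f"C{i:0{id_width}d}"
        sex = "female" if rng.random() < 0.5 else "male"
        arm = config.arm_labels[int(rng.integers(len(config.arm_labels)))]

        # shared frailty couples the intercept with all segment velocities
        z_int = rng.standard_normal()
        z_ind = rng.standard_normal()
        frailty = rho * z_int + np.sqrt(max(0.0, 1.0 - rho ** 2)) * z_ind
        eps = rng.standard_normal(N_BLOCKS)
        seg_v = seg_means + seg_sds * (lam * frailty
                                       + np.sqrt(max(0.0, 1.0 - lam ** 2)) * eps)
        intercept = intercept_mean + config.latent_intercept_sd_cm * z_int

        # visit schedule (planned indices; some visits after the first missed)
        a0_mo = max(4.0, rng.normal(config.enrollment_age_mean_mo,
                                    config.enrollment_age_sd_mo))
        gaps = config.visit_interval_days_mean + rng.normal(
            0.0, config.visit_interval_jitter_sd_days, config.n_visits_target - 1)
        gaps = np.clip(gaps, 7.0, None)
        age_days = a0_mo * DAYS_PER_MONTH + np.concatenate([[0.0], np.cumsum(gaps)])
        keep = np.concatenate([[True],
                               rng.random(config.n_visits_target - 1)
                               >= config.missing_visit_prob])

        spells = _draw_spells(rng, config.n_visits_target - 1,
                              config.episode_rate_per_visit,
                              config.episode_duration_geometric_p)
        in_spell = np.zeros(config.n_visits_target, dtype=bool)
        for s, d in spells:
            in_spell[s:s + d] = True

        # latent length with episode deficits applied to the growth into
        # each in-spell visit; lost growth is never recovered
        age_mo = age_days / DAYS_PER_MONTH
        base = latent_fn(age_mo, intercept, seg_v)
        incr = np.diff(base)
        deficit = config.episode_velocity_deficit_cm_mo * np.diff(age_mo)
        incr = incr - np.where(in_spell[1:], deficit, 0.0)
        latent_len = base[0] + np.concatenate([[0.0], np.cumsum(incr)])

        err = rng.normal(0.0, config.measurement_error_sd_cm,
                         (config.n_visits_target, 2))
        noise = err.mean(axis=1) if config.duplicate_measure else err[:, 0]
        observed = latent_len + noise

        ill_p = np.where(in_spell, config.illness_link_prob,
                         config.illness_background_prob)
        illness = (rng.random(config.n_visits_target) < ill_p).astype(int)

        enroll_date = start + pd.Timedelta(
            days=int(cohort_rng.integers(config.enrollment_window_days + 1)))

        for t in range(config.n_visits_target):
            if not keep[t]:
                continue
            rows.append((
                child_id, sex, arm, t,
                (enroll_date + pd.Timedelta(days=round(age_days[t] - age_days[0]))
                 ).date().isoformat(),
                age_days[t], observed[t], illness[t],
            ))
        latents.append(LatentChild(child_id, sex, arm, float(intercept),
                                   seg_v.copy(), spells))

    panel = pd.DataFrame(rows, columns=[
        "child_id", "sex", "arm", "visit_index", "date",
        "age_days", "length_cm", "illness_reported"])
    return panel, latents


def latents_to_frame(latents) -> pd.DataFrame:
    """Latent truth as a flat table (spells JSON-encoded), for CSV export."""
    recs = []
    for lc in latents:
        rec = {"child_id": lc.child_id, "sex": lc.sex, "arm": lc.arm,
               "latent_intercept_cm": lc.latent_intercept_cm}
        for j, v in enumerate(lc.latent_segment_velocities):
            rec[f"latent_v{j + 1}"] = v
        rec["episode_spells"] = json.dumps([list(s) for s in lc.episode_spells])
        recs.append(rec)
    return pd.DataFrame(recs)


def simulate_episode_regression_cohort(
        n_children: int,
        seed: int,
        effect_cm: float = -1.7,
        effect_on: str = "any_two_consecutive",
        arm_labels=DEFAULT_ARM_LABELS,
        arm_effects_cm=(0.0, -0.8, 0.07, -0.19),
        illness_effect_cm: float = -0.10,
        first_length_effect: float = 0.94,
        noise_sd_cm: float = 2.0):
    """Child-level episode summaries with a *known* planted effect.

    Generates per-child slow-growth summaries, covariates, and an attained
    length drawn from the exact regression model the episode analysis fits,
    so the fitted coefficient on ``effect_on`` has ``effect_cm`` as its
    true value. This is the parameter-recovery and type-I-error oracle for
    :func:`growthfalter.episodes.fit_episode_regressions`.

    Returns a DataFrame with columns ``child_id, any_two_consecutive,
    n_slow_months, longest_run, arm, illness_total, first_length_cm,
    attained_length_cm``.
    """
    if effect_on not in ("any_two_consecutive", "n_slow_months", "longest_run"):
        raise ValueError(f"unknown effect_on {effect_on!r}")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(7,)))
    n_slow = rng.poisson(2.8, n_children)
    longest = np.where(n_slow == 0, 0,
                       1 + rng.binomial(np.maximum(n_slow - 1, 0), 0.18))
    any2 = (longest >= 2).astype(int)
    arm_idx = rng.integers(len(arm_labels), size=n_children)
    illness = rng.poisson(3.0, n_children)
    first_len = rng.normal(65.6, 2.6, n_children)

    exposure = {"any_two_consecutive": any2, "n_slow_months": n_slow,
                "longest_run": longest}[effect_on]
    arm_fx = np.asarray(arm_effects_cm)[arm_idx % len(arm_effects_cm)]
    attained = (20.0 + effect_cm * exposure + arm_fx
                + illness_effect_cm * illness
                + first_length_effect * first_len
                + rng.normal(0.0, noise_sd_cm, n_children))
    return pd.DataFrame({
        "child_id": [f"C{i:05d}" for i in range(n_children)],
        "any_two_consecutive": any2.astype(bool),
        "n_slow_months": n_slow,
        "longest_run": longest,
        "arm": np.asarray(arm_labels)[arm_idx],
        "illness_total": illness,
        "first_length_cm": first_len,
        "attained_length_cm": attained,
    })
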