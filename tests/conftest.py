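import numpy as np
import pandas as pd
import pytest

from growthfalter import (SimulationConfig, generate_reference,
                          simulate_cohort, filter_implausible)


@pytest.fixture(scope="session")
def reference():
    return generate_reference(seed=1)


@pytest.fixture(scope="session")
def noiseless_cohort(reference):
    """Exactly piecewise-linear trajectories: no noise, no episodes."""
    cfg = SimulationConfig(n_children=40, seed=11,
                           measurement_error_sd_cm=0.0,
                           episode_rate_per_visit=0.0,
                           missing_visit_prob=0.0)
    panel, latents = simulate_cohort(cfg, reference)
    return panel, latents


@pytest.fixture(scope="session")
def noisy_cohort(reference):
    cfg = SimulationConfig(n_children=120, seed=23)
    panel, latents = simulate_cohort(cfg, reference)
    return panel, latents


@pytest.fixture(scope="session")
def derived_cohort(noisy_cohort, reference):
    panel, _ = noisy_cohort
    derived, _ = filter_implausible(panel, reference)
    return derived


def make_manual_panel(rows):
    """Small hand-built panel; rows = (child, sex, visit, age_days, length)."""
    return pd.DataFrame(
        [{"child_id": c, "sex": s, "arm": "CSB+", "visit_index": v,
          "date": "2015-01-01", "age_days": a, "length_cm": l,
          "illness_reported": 0} for c, s, v, a, l in rows])
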