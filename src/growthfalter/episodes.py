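"""Slow-growth episode detection and its attained-length regressions.

A child-month is "slow" when its length velocity falls strictly below the
chosen centile of velocities among children of the same (integer-month)
age. The working cutoff is selected as the lowest candidate centile at
which more than a target fraction (default 95%) of children have at least
one slow month. Maximal runs of consecutive slow months form episodes;
runs break at missed-visit gaps longer than ``max_gap_days``. A
sensitivity definition flags negative residuals from a pooled regression
of length on the spline age basis conditional on initial length.

Episode summaries per child (any >=2-consecutive spell, total slow months,
longest run, age block of first onset) feed OLS regressions of attained
length adjusted for study arm, total reported illness episodes, and length
at first measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .curves import build_design
from .errors import SingularModelError, ThresholdSelectionError
from .stage2 import SecondStageFit, _stars
from .units import DAYS_PER_MONTH

ONSET_BLOCKS = ("never", "7-8", "9-11", "12-14", "15-17",
                "18-20", "21-23", "24-28")


def _onset_block(age_mo: float) -> str:
    if age_mo < 9:
        return "7-8"
    for lo in (9, 12, 15, 18, 21):
        if age_mo < lo + 3:
            return f"{lo}-{lo + 2}"
    return "24-28"


def assign_age_bins(age_days, min_bin_n: int = 30):
    """Integer-month age bin per observation, merging sparse bins outward.

    The bin is the nearest whole month of age at the velocity's later
    endpoint. Bins with fewer than ``min_bin_n`` observations are merged
    into their nearest populated neighbour (lower month on ties) until all
    remaining bins meet the minimum; the merge map is returned for the run
    manifest.
    """
    months = np.rint(np.asarray(age_days, dtype=float) / DAYS_PER_MONTH
                     ).astype(int)
    mapping = {int(m): int(m) for m in np.unique(months)}

    def counts():
        eff = np.array([mapping[m] for m in months])
        return pd.Series(eff).value_counts().sort_index()

    while True:
        c = counts()
        small = c[c < min_bin_n]
        if small.empty or len(c) == 1:
            break
        m = int(small.index[0])
        others = [b for b in c.index if b != m]
        target = min(others, key=lambda b: (abs(b - m), b))
        for k, v in mapping.items():
            if v == m:
                mapping[k] = int(target)
        warnings.warn(f"age bin {m} mo has <{min_bin_n} velocity "
                      f"observations; merged into bin {target} mo",
                      stacklevel=2)
    return np.array([mapping[m] for m in months]), mapping


def velocity_centile_flags(panel: pd.DataFrame, cutoff_centile: float,
                           min_bin_n: int = 30) -> pd.Series:
    """Boolean slow-growth flag per observation.

    True iff the observation's velocity is strictly below the rank-
    interpolated ``cutoff_centile`` of velocities in its age bin. First
    visits (no velocity) are never flagged. ``cutoff_centile=0`` flags
    nothing (no value is strictly below the minimum).
    """
    flags = pd.Series(False, index=panel.index)
    has_v = panel["velocity_cm_mo"].notna()
    sub = panel[has_v]
    if len(sub) == 0:
        return flags
    bins, _ = assign_age_bins(sub["age_days"].to_numpy(), min_bin_n)
    v = sub["velocity_cm_mo"].to_numpy()
    out = np.zeros(len(sub), dtype=bool)
    for b in np.unique(bins):
        m = bins == b
        cut = np.percentile(v[m], cutoff_centile, method="linear")
        out[m] = v[m] < cut
    flags.loc[sub.index] = out
    return flags


def coverage_at(panel: pd.DataFrame, flags: pd.Series) -> float:
    """Fraction of children with at least one flagged month."""
    per_child = flags.groupby(panel["child_id"]).any()
    return float(per_child.mean())


def select_threshold(panel: pd.DataFrame, coverage: float = 0.95,
                     candidate_centiles=range(1, 51), min_bin_n: int = 30):
    """Smallest candidate centile whose child coverage strictly exceeds
    ``coverage``; also returns the full coverage-vs-centile curve.

    Coverage is the fraction of children with >=1 slow month at that
    cutoff; it is non-decreasing in the centile, so the feasibility set is
    an upper interval and the minimum is well defined. Raises
    :class:`ThresholdSelectionError` if no candidate reaches coverage.
    """
    rows, chosen = [], None
    for c in candidate_centiles:
        cov = coverage_at(panel, velocity_centile_flags(panel, c, min_bin_n))
        rows.append({"centile": c, "coverage": cov})
        if chosen is None and cov > coverage:
            chosen = c
    curve = pd.DataFrame(rows)
    if chosen is None:
        raise ThresholdSelectionError(float(curve["coverage"].max()))
    return chosen, curve


@dataclass
class SlowGrowthEpisode:
    child_id: object
    start_visit_index: int
    start_age_mo: float
    run_length: int
    threshold_kind: str = "centile"


def _maximal_runs(flags, breaks):
    """Maximal runs of True in ``flags``; ``breaks[i]`` True means a run
    may not span positions i-1 -> i. Returns (start_position, length)."""
    runs = []
    start = None
    for i, f in enumerate(flags):
        if start is not None and breaks[i]:
            runs.append((start, i - start))
            start = None
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(flags) - start))
    return runs


def detect_runs(panel: pd.DataFrame, flags: pd.Series,
                max_gap_days: float = 45.0,
                threshold_kind: str = "centile") -> list:
    """Run-length-encode flagged visits into :class:`SlowGrowthEpisode`s.

    Within each child, visits are taken in age order; a gap between
    consecutive visits exceeding ``max_gap_days`` breaks a run, as does a
    visit with no velocity (which can never be flagged).
    """
    episodes = []
    df = panel.assign(_slow=flags.to_numpy()).sort_values(
        ["child_id", "age_days"])
    for child_id, grp in df.groupby("child_id", sort=True):
        fl = grp["_slow"].to_numpy()
        gaps = np.diff(grp["age_days"].to_numpy(), prepend=np.nan)
        breaks = np.zeros(len(grp), dtype=bool)
        breaks[1:] = gaps[1:] > max_gap_days
        for pos, length in _maximal_runs(fl, breaks):
            row = grp.iloc[pos]
            episodes.append(SlowGrowthEpisode(
                child_id, int(row["visit_index"]),
                float(row["age_days"]) / DAYS_PER_MONTH, int(length),
                threshold_kind))
    return episodes


def residual_flags(panel: pd.DataFrame, flavor: str = "pooled",
                   knots=None) -> pd.Series:
    """Sensitivity flag: negative residual from a length-on-age regression.

    ``flavor='pooled'`` (default): one OLS of length on the 6-knot spline
    age basis plus each child's length at their first retained visit,
    pooled over all observations; an observation is flagged iff its
    residual is negative. ``flavor='per_child'`` instead flags negative
    residuals from each child's own spline fit (these sum to ~0 per child
    by construction, so roughly half of every child's months flag).
    """
    df = panel.sort_values(["child_id", "age_days"])
    ages_mo = df["age_days"].to_numpy() / DAYS_PER_MONTH
    y = df["length_cm"].to_numpy()
    if flavor == "pooled":
        X, _ = build_design(ages_mo, "linear_spline_6", knots)
        first_len = df.groupby("child_id")["length_cm"].transform("first")
        X = np.column_stack([X, first_len.to_numpy()])
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
    elif flavor == "per_child":
        resid = np.empty(len(df))
        pos = 0
        for _, grp in df.groupby("child_id", sort=True):
            a = grp["age_days"].to_numpy() / DAYS_PER_MONTH
            Xc, _ = build_design(a, "linear_spline_6", knots)
            yc = grp["length_cm"].to_numpy()
            b, _, _, _ = np.linalg.lstsq(Xc, yc, rcond=None)
            resid[pos:pos + len(grp)] = yc - Xc @ b
            pos += len(grp)
    else:
        raise ValueError(f"unknown flavor {flavor!r}")
    flags = pd.Series(resid < 0, index=df.index)
    # first visits carry no velocity and are not eligible months
    flags[panel["velocity_cm_mo"].isna()] = False
    return flags.reindex(panel.index)


def summarize_episodes(episodes, panel: pd.DataFrame) -> pd.DataFrame:
    """Per-child episode summary table.

    Columns: n_slow_months (total flagged months), n_episodes,
    n_two_consecutive_runs, any_two_consecutive, longest_run,
    first_onset_age_block ('never' for episode-free children). Every child
    in the panel appears, episodes or not.
    """
    rows = {cid: {"child_id": cid, "n_slow_months": 0, "n_episodes": 0,
                  "n_two_consecutive_runs": 0, "any_two_consecutive": False,
                  "longest_run": 0, "first_onset_age_mo": np.nan,
                  "first_onset_age_block": "never"}
            for cid in panel["child_id"].unique()}
    for ep in episodes:
        r = rows[ep.child_id]
        r["n_slow_months"] += ep.run_length
        r["n_episodes"] += 1
        r["longest_run"] = max(r["longest_run"], ep.run_length)
        if ep.run_length >= 2:
            r["n_two_consecutive_runs"] += 1
            r["any_two_consecutive"] = True
        if (np.isnan(r["first_onset_age_mo"])
                or ep.start_age_mo < r["first_onset_age_mo"]):
            r["first_onset_age_mo"] = ep.start_age_mo
            r["first_onset_age_block"] = _onset_block(ep.start_age_mo)
    return pd.DataFrame(list(rows.values())).sort_values(
        "child_id").reset_index(drop=True)


def episode_quintile_summary(summaries: pd.DataFrame,
                             attained: pd.DataFrame,
                             flags: pd.Series,
                             panel: pd.DataFrame) -> pd.DataFrame:
    """Frequency/duration of slow growth by attained-length quintile:
    flagged months (n, % of velocity months), children with >=1 slow month
    and with >=1 two-consecutive spell (n, %), mean slow months and mean
    longest run per child."""
    df = summaries.merge(attained[["child_id", "quintile"]], on="child_id")
    obs = panel.assign(_slow=flags.to_numpy()).merge(
        attained[["child_id", "quintile"]], on="child_id")
    obs = obs[obs["velocity_cm_mo"].notna()]
    rows = []
    groups = [("overall", df, obs)] + [
        (q, df[df["quintile"] == q], obs[obs["quintile"] == q])
        for q in sorted(df["quintile"].unique())]
    for label, d, o in groups:
        rows.append({
            "group": label,
            "n_children": len(d),
            "n_velocity_months": len(o),
            "slow_months_n": int(o["_slow"].sum()),
            "slow_months_pct": 100.0 * o["_slow"].mean() if len(o) else np.nan,
            "children_any_slow_n": int((d["n_slow_months"] > 0).sum()),
            "children_any_slow_pct": 100.0 * (d["n_slow_months"] > 0).mean(),
            "children_two_consecutive_n": int(d["any_two_consecutive"].sum()),
            "children_two_consecutive_pct":
                100.0 * d["any_two_consecutive"].mean(),
            "mean_slow_months": d["n_slow_months"].mean(),
            "sd_slow_months": d["n_slow_months"].std(ddof=1),
            "mean_longest_run": d["longest_run"].mean(),
            "sd_longest_run": d["longest_run"].std(ddof=1),
        })
    return pd.DataFrame(rows)


def build_child_covariates(panel: pd.DataFrame,
                           attained: pd.DataFrame) -> pd.DataFrame:
    """Child-level covariates for the episode regressions: study arm,
    total reported illness episodes, and length at first retained visit."""
    df = panel.sort_values(["child_id", "age_days"])
    first = df.groupby("child_id").first()
    ill = df.groupby("child_id")["illness_reported"].sum()
    cov = pd.DataFrame({
        "child_id": first.index,
        "arm": first["arm"].to_numpy(),
        "illness_total": ill.to_numpy(),
        "first_length_cm": first["length_cm"].to_numpy(),
    })
    return cov.merge(attained[["child_id", "attained_length_cm"]],
                     on="child_id")


def _fit_formula(df, exposure_term, label, arm_reference):
    formula = (f"attained_length_cm ~ {exposure_term} "
               f"+ C(arm, Treatment(reference={arm_reference!r})) "
               f"+ illness_total + first_length_cm")
    try:
        res = smf.ols(formula, data=df).fit()
    except Exception as exc:  # pragma: no cover - statsmodels wraps errors
        raise SingularModelError(f"{label}: {exc}") from exc
    terms = [t for t in res.params.index if t != "Intercept"]
    ci = res.conf_int()
    return SecondStageFit(
        model_id=label, terms=terms,
        params={t: float(res.params[t]) for t in terms},
        se={t: float(res.bse[t]) for t in terms},
        conf_low={t: float(res.params[t] - 1.96 * res.bse[t]) for t in terms},
        conf_high={t: float(res.params[t] + 1.96 * res.bse[t]) for t in terms},
        pvalues={t: float(res.pvalues[t]) for t in terms},
        r_squared=float(res.rsquared), n=int(res.nobs))


def fit_episode_regressions(summaries: pd.DataFrame,
                            covariates: pd.DataFrame,
                            arm_reference: str | None = None) -> dict:
    """OLS of attained length on each slow-growth exposure, adjusted.

    Fits four models, each adjusted for study arm (reference = first arm
    label unless given), total illness episodes, and length at first
    measurement:

    - ``any_two_consecutive``: indicator of >=1 two-consecutive spell;
    - ``n_slow_months``: total slow months;
    - ``longest_run``: longest spell length (months);
    - ``onset``: indicators for the age block of first onset
      (reference = never slow).

    Returns a dict label -> :class:`SecondStageFit`. Raises ``KeyError``
    naming any missing covariate column.
    """
    for col in ("arm", "illness_total", "first_length_cm",
                "attained_length_cm"):
        if col not in covariates.columns:
            raise KeyError(f"covariates missing required column {col!r}")
    df = summaries.merge(covariates, on="child_id", validate="one_to_one")
    df["any_two_consecutive"] = df["any_two_consecutive"].astype(int)
    if arm_reference is None:
        arm_reference = str(df["arm"].iloc[0]) if "arm" in df else ""
    out = {}
    for label, term in [("any_two_consecutive", "any_two_consecutive"),
                        ("n_slow_months", "n_slow_months"),
                        ("longest_run", "longest_run")]:
        out[label] = _fit_formula(df, term, label, arm_reference)
    present = [b for b in ONSET_BLOCKS
               if b in set(df["first_onset_age_block"])]
    df["first_onset_age_block"] = pd.Categorical(
        df["first_onset_age_block"], categories=present)
    out["onset"] = _fit_formula(
        df, "C(first_onset_age_block, Treatment(reference='never'))",
        "onset", arm_reference)
    return out


def episode_regression_table(fits: dict) -> pd.DataFrame:
    rows = []
    for label, fit in fits.items():
        for t in fit.terms:
            rows.append({"model": label, "term": t, "coef": fit.params[t],
                         "se": fit.se[t], "ci_low": fit.conf_low[t],
                         "ci_high": fit.conf_high[t],
                         "pvalue": fit.pvalues[t],
                         "stars": _stars(fit.pvalues[t]),
                         "r_squared": fit.r_squared, "n": fit.n})
    return pd.DataFrame(rows)
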