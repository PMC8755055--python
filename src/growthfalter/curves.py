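"""Stage 1: per-child growth-curve regressions of length on age.

Each child's recumbent length is regressed on age (months) by ordinary
least squares in one of four functional forms:

* ``linear_spline_6`` — truncated linear spline, knots at 9, 12, 15, 18,
  21, 24 mo (the primary form):
  length = b0 + b1*age + sum_k c_k*(age - knot_k)+
* ``linear_spline_4`` — same basis with 4 knots (default evenly spaced
  over the observed 6-27 mo span at 10.2, 14.4, 18.6, 22.8 mo);
* ``cubic_poly`` — polynomial in age up to the cubic term;
* ``restricted_cubic`` — natural (restricted) cubic spline, linear in the
  tails, default 5 knots at the {5, 27.5, 50, 72.5, 95}% quantiles of the
  pooled age distribution.

From each fit we extract the quantities the second stage uses: the
intercept (initial length; by default the raw age-0 intercept, optionally
re-centered so it reads as length at 6 mo), R^2 as growth-curve
smoothness, the overall F statistic, AIC/BIC for form comparison, and the
seven age-block segment velocities (6-8, 9-11, ..., 21-23, 24-end months).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CurveFitError
from .simulate import BLOCK_STARTS_MO
from .units import DAYS_PER_MONTH

KNOTS_6 = (9.0, 12.0, 15.0, 18.0, 21.0, 24.0)
KNOTS_4 = (10.2, 14.4, 18.6, 22.8)
RCS_KNOT_QUANTILES = (5.0, 27.5, 50.0, 72.5, 95.0)

FORMS = ("linear_spline_6", "linear_spline_4", "cubic_poly", "restricted_cubic")

VELOCITY_COLUMNS = ("v_6_8", "v_9_11", "v_12_14", "v_15_17",
                    "v_18_20", "v_21_23", "v_24_28")


@dataclass(frozen=True)
class SplineBasis:
    """Truncated linear spline basis: age plus (age - knot)+ terms."""

    knots: tuple = KNOTS_6

    def __post_init__(self):
        k = tuple(float(x) for x in self.knots)
        if any(b <= a for a, b in zip(k, k[1:])):
            raise ValueError("knots must be strictly increasing")
        object.__setattr__(self, "knots", k)


def truncated(age_mo, knot):
    """(age - knot)+, exactly zero for age <= knot."""
    return np.maximum(np.asarray(age_mo, dtype=float) - knot, 0.0)


def _rcs_terms(x, knots):
    # Restricted (natural) cubic spline truncated-power basis; linear
    # beyond the boundary knots. Yields len(knots)-2 nonlinear columns.
    t = np.asarray(knots, dtype=float)
    k = len(t)
    scale = (t[-1] - t[0]) ** 2
    cols = []
    for j in range(k - 2):
        term = (truncated(x, t[j]) ** 3
                - truncated(x, t[-2]) ** 3 * (t[-1] - t[j]) / (t[-1] - t[-2])
                + truncated(x, t[-1]) ** 3 * (t[-2] - t[j]) / (t[-1] - t[-2]))
        cols.append(term / scale)
    return cols


def build_design(ages_mo, form="linear_spline_6", knots=None,
                 center_age_at: float = 0.0):
    """Design matrix for one functional form.

    Returns ``(X, column_names)``. Columns are ordered constant, age, then
    truncated/polynomial/spline terms with knots ascending. Only the age
    column is shifted by ``center_age_at``; truncated terms stay on the
    raw age scale, so with ``center_age_at=c`` below the first knot the
    intercept is the fitted length at age ``c``.
    """
    a = np.asarray(ages_mo, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("ages must be finite")
    const = np.ones_like(a)
    age_col = a - center_age_at
    if form in ("linear_spline_6", "linear_spline_4"):
        if knots is None:
            knots = KNOTS_6 if form == "linear_spline_6" else KNOTS_4
        knots = SplineBasis(knots).knots
        cols = [const, age_col] + [truncated(a, k) for k in knots]
        names = ["const", "age"] + [f"spline_{k:g}" for k in knots]
    elif form == "cubic_poly":
        cols = [const, age_col, age_col ** 2, age_col ** 3]
        names = ["const", "age", "age2", "age3"]
    elif form == "restricted_cubic":
        if knots is None:
            knots = tuple(np.percentile(a, RCS_KNOT_QUANTILES))
        knots = tuple(float(k) for k in knots)
        cols = [const, age_col] + _rcs_terms(a, knots)
        names = ["const", "age"] + [f"rcs_{j + 1}" for j in range(len(knots) - 2)]
    else:
        raise ValueError(f"unknown functional form {form!r}")
    return np.column_stack(cols), names


@dataclass
class ChildCurveFit:
    """OLS results and extracted parameters for one child."""

    child_id: object
    form: str
    coefficients: np.ndarray
    column_names: list
    knots: tuple
    center_age_at: float
    intercept: float
    age_slope: float
    knot_weights: np.ndarray
    segment_velocities: np.ndarray  # one per age block, cm/mo
    r_squared: float
    f_statistic: float
    n_obs: int
    aic: float
    bic: float
    final_age_mo: float
    residuals: np.ndarray = field(repr=False, default=None)

    def fitted(self, ages_mo):
        """Evaluate the fitted curve at arbitrary ages (months)."""
        X, _ = build_design(ages_mo, self.form, self.knots, self.center_age_at)
        out = X @ self.coefficients
        return float(out[0]) if np.ndim(ages_mo) == 0 else out


def _block_edges(final_age_mo: float):
    end = max(float(final_age_mo), BLOCK_STARTS_MO[-1] + 1.0)
    return list(BLOCK_STARTS_MO) + [end]


def segment_velocities_from_spline(age_slope, knot_weights, knots=KNOTS_6):
    """Slope in each age block for a truncated-linear-spline fit with knots
    at the block boundaries: v_block = b1 + sum of weights of knots at or
    below the block start."""
    v = []
    for start in BLOCK_STARTS_MO:
        v.append(age_slope + sum(w for k, w in zip(knots, knot_weights)
                                 if k <= start))
    return np.asarray(v)


def fit_child_curve(ages_mo, lengths_cm, form="linear_spline_6",
                    child_id=None, knots=None,
                    center_age_at: float = 0.0) -> ChildCurveFit:
    """OLS fit of one child's length on age in the requested form.

    Raises :class:`CurveFitError` naming the child when the design is rank
    deficient (e.g. no observations beyond a knot) or there are fewer than
    parameters + 1 observations.
    """
    a = np.asarray(ages_mo, dtype=float)
    y = np.asarray(lengths_cm, dtype=float)
    X, names = build_design(a, form, knots, center_age_at)
    n, p = X.shape
    if n < p + 1:
        raise CurveFitError(child_id, f"{n} observations for {p} parameters "
                                      f"(need >= {p + 1})")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise CurveFitError(child_id,
                            f"rank-deficient design (rank {rank} < {p}) "
                            f"for form {form!r}")
    resid = y - X @ beta
    ssr = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - ssr / sst
    df_model, df_resid = p - 1, n - p
    if ssr <= 1e-24 * max(sst, 1.0):
        f_stat = np.inf
    else:
        f_stat = ((sst - ssr) / df_model) / (ssr / df_resid)
    sigma2 = max(ssr / n, 1e-300)
    llf = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    aic = -2.0 * llf + 2.0 * p
    bic = -2.0 * llf + p * np.log(n)

    if form in ("linear_spline_6", "linear_spline_4"):
        used_knots = (SplineBasis(knots).knots if knots is not None
                      else (KNOTS_6 if form == "linear_spline_6" else KNOTS_4))
        kw = beta[2:]
    elif form == "restricted_cubic":
        used_knots = (tuple(float(k) for k in knots) if knots is not None
                      else tuple(np.percentile(a, RCS_KNOT_QUANTILES)))
        kw = beta[2:]
    else:
        used_knots = ()
        kw = beta[2:]

    fit = ChildCurveFit(
        child_id=child_id, form=form, coefficients=beta, column_names=names,
        knots=used_knots, center_age_at=center_age_at,
        intercept=float(beta[0]), age_slope=float(beta[1]),
        knot_weights=np.asarray(kw), segment_velocities=None,
        r_squared=float(r2), f_statistic=float(f_stat), n_obs=n,
        aic=float(aic), bic=float(bic), final_age_mo=float(a.max()),
        residuals=resid)

    if form == "linear_spline_6" and tuple(used_knots) == KNOTS_6:
        fit.segment_velocities = segment_velocities_from_spline(
            fit.age_slope, fit.knot_weights, used_knots)
    else:
        # mean slope over each block from the fitted curve itself
        edges = _block_edges(fit.final_age_mo)
        vals = fit.fitted(np.asarray(edges))
        fit.segment_velocities = np.diff(vals) / np.diff(edges)
    return fit


def fit_cohort_curves(panel: pd.DataFrame, form="linear_spline_6",
                      knots=None, center_age_at: float = 0.0,
                      on_error: str = "collect"):
    """Fit every child in a panel; returns ``(fits, failures)``.

    ``failures`` maps child_id -> error message; with ``on_error='raise'``
    the first failure propagates instead. Failed children are reported,
    never silently dropped.
    """
    fits, failures = [], {}
    for child_id, grp in panel.sort_values(["child_id", "age_days"]
                                           ).groupby("child_id", sort=True):
        ages = grp["age_days"].to_numpy() / DAYS_PER_MONTH
        try:
            fits.append(fit_child_curve(ages, grp["length_cm"].to_numpy(),
                                        form, child_id, knots, center_age_at))
        except CurveFitError as exc:
            if on_error == "raise":
                raise
            failures[child_id] = str(exc)
    return fits, failures


def extract_stage1_table(fits) -> pd.DataFrame:
    """One row per child: intercept, R^2, F, the 7 segment velocities,
    AIC/BIC and n. All fits must share one functional form."""
    forms = {f.form for f in fits}
    if len(forms) > 1:
        raise ValueError(f"fits mix functional forms: {sorted(forms)}")
    rows = []
    for f in fits:
        row = {"child_id": f.child_id, "form": f.form,
               "intercept": f.intercept, "r_squared": f.r_squared,
               "f_statistic": f.f_statistic}
        for name, v in zip(VELOCITY_COLUMNS, f.segment_velocities):
            row[name] = v
        row.update(aic=f.aic, bic=f.bic, n_obs=f.n_obs)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class FormComparison:
    table: pd.DataFrame
    selected_form: str       # lowest child-averaged BIC
    aic_selected_form: str   # lowest child-averaged AIC


def compare_forms(panel: pd.DataFrame, forms=FORMS, knots_by_form=None,
                  center_age_at: float = 0.0,
                  min_fit_fraction: float = 0.95) -> FormComparison:
    """Child-averaged AIC/BIC per candidate functional form.

    Restricted-cubic knots default to pooled-age quantiles. Averages are
    taken over children fittable under *every* form so the criteria are
    comparable; a form fittable for less than ``min_fit_fraction`` of
    children triggers a warning.
    """
    knots_by_form = dict(knots_by_form or {})
    if "restricted_cubic" in forms and "restricted_cubic" not in knots_by_form:
        pooled = panel["age_days"].to_numpy() / DAYS_PER_MONTH
        knots_by_form["restricted_cubic"] = tuple(
            np.percentile(pooled, RCS_KNOT_QUANTILES))
    per_form = {}
    n_children = panel["child_id"].nunique()
    for form in forms:
        fits, failures = fit_cohort_curves(
            panel, form, knots_by_form.get(form), center_age_at)
        if n_children and len(fits) < min_fit_fraction * n_children:
            warnings.warn(f"form {form!r} fit only {len(fits)}/{n_children} "
                          f"children", stacklevel=2)
        per_form[form] = {f.child_id: f for f in fits}
    common = set.intersection(*(set(d) for d in per_form.values())) \
        if per_form else set()
    rows = []
    for form in forms:
        fs = [per_form[form][c] for c in sorted(common)]
        rows.append({
            "form": form,
            "mean_aic": float(np.mean([f.aic for f in fs])) if fs else np.nan,
            "mean_bic": float(np.mean([f.bic for f in fs])) if fs else np.nan,
            "n_parameters": len(per_form[form][next(iter(common))].coefficients)
            if common else np.nan,
            "n_children": len(fs),
        })
    table = pd.DataFrame(rows)
    sel = table.loc[table["mean_bic"].idxmin(), "form"]
    sel_aic = table.loc[table["mean_aic"].idxmin(), "form"]
    return FormComparison(table, str(sel), str(sel_aic))
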