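"""Stage 2: attained length regressed on extracted growth-curve parameters.

The nested model sequence adds one predictor at a time to an OLS of each
child's attained length (cm, at the final visit) on their stage-1
parameters: Model 1 uses growth-curve smoothness (R^2) alone, Model 2 adds
initial length (the stage-1 intercept), and Models 3-9 add the seven age-
block segment velocities in age order. The R^2 predictor is rescaled by
100 before fitting so its coefficient reads "cm of attained length per
0.01 increase in R^2".

Also provides the grouped descriptive tables (mean +/- SD by attained-
length quintile with one-way ANOVA / chi-square and Bonferroni-adjusted
pairwise comparisons) and kernel-density summaries of LAZ by quintile at
selected ages, exported as tabular curves.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .curves import VELOCITY_COLUMNS
from .errors import SingularModelError
from .units import DAYS_PER_MONTH

#: Predictor sets for Models 1..9 (cumulative).
MODEL_TERMS = [["r_squared"],
               ["r_squared", "intercept"]] + [
    ["r_squared", "intercept"] + list(VELOCITY_COLUMNS[:j + 1])
    for j in range(len(VELOCITY_COLUMNS))
]


def _stars(p):
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


@dataclass
class SecondStageFit:
    """One fitted model of the nested sequence."""

    model_id: int
    terms: list
    params: dict          # term -> coefficient (cm per predictor unit)
    se: dict
    conf_low: dict
    conf_high: dict
    pvalues: dict
    r_squared: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"term": t, "coef": self.params[t], "se": self.se[t],
                 "ci_low": self.conf_low[t], "ci_high": self.conf_high[t],
                 "pvalue": self.pvalues[t],
                 "stars": _stars(self.pvalues[t])} for t in self.terms]
        df = pd.DataFrame(rows)
        df.insert(0, "model", self.model_id)
        return df


def _ols_fit(y, X, model_label):
    Xm = np.column_stack([np.ones(len(y))] + [X[c].to_numpy() for c in X])
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise SingularModelError(
            f"{model_label}: collinear predictors {list(X.columns)}")
    res = sm.OLS(y, Xm).fit()
    return res


def fit_model_sequence(stage1: pd.DataFrame, attained: pd.DataFrame,
                       rescale_r2: bool = True) -> list:
    """Fit Models 1-9 and return a list of :class:`SecondStageFit`.

    ``stage1`` is the per-child parameter table from
    :func:`growthfalter.curves.extract_stage1_table`; ``attained`` the
    per-child table from :func:`growthfalter.indices.attained_length`.
    Confidence intervals are large-sample normal (coefficient +/- 1.96 SE)
    with homoskedastic OLS standard errors.
    """
    df = stage1.merge(attained[["child_id", "attained_length_cm"]],
                      on="child_id", validate="one_to_one")
    missing = df[["intercept", "r_squared"] + list(VELOCITY_COLUMNS)].isna()
    if missing.any().any():
        raise ValueError("stage-1 table has missing parameters")
    work = df.copy()
    if rescale_r2:
        work["r_squared"] = work["r_squared"] * 100.0  # per 0.01 units
    y = work["attained_length_cm"].to_numpy()
    fits = []
    for m, terms in enumerate(MODEL_TERMS, start=1):
        res = _ols_fit(y, work[terms], f"Model {m}")
        names = ["const"] + terms
        params = dict(zip(names, res.params))
        se = dict(zip(names, res.bse))
        pv = dict(zip(names, res.pvalues))
        fits.append(SecondStageFit(
            model_id=m, terms=terms,
            params={t: params[t] for t in terms},
            se={t: se[t] for t in terms},
            conf_low={t: params[t] - 1.96 * se[t] for t in terms},
            conf_high={t: params[t] + 1.96 * se[t] for t in terms},
            pvalues={t: pv[t] for t in terms},
            r_squared=float(res.rsquared), n=int(res.nobs)))
    return fits


def model_sequence_table(fits) -> pd.DataFrame:
    """Wide table mirroring the nested-model layout: one row per predictor,
    one column block per model, plus model R^2 and n."""
    long = pd.concat([f.to_frame() for f in fits], ignore_index=True)
    wide = long.pivot(index="term", columns="model", values="coef")
    order = [t for t in MODEL_TERMS[-1] if t in wide.index]
    wide = wide.loc[order]
    meta = pd.DataFrame(
        {f.model_id: {"r_squared_model": f.r_squared, "n": f.n}
         for f in fits}).T
    return wide, long, meta


def _group(grouped, key):
    # pandas deprecates scalar get_group keys for list-like groupers
    return grouped.get_group(key if isinstance(key, tuple) else (key,))


def quintile_descriptives(data: pd.DataFrame, variables,
                          group: str | list = "quintile",
                          categorical=()) -> pd.DataFrame:
    """Grouped descriptives with ANOVA / chi-square and Bonferroni pairs.

    ``data`` must carry the grouping column(s) plus the requested
    variables (one row per child). Continuous variables get mean +/- SD
    per group, a one-way ANOVA F and p, and Bonferroni-adjusted pairwise
    t-test p-values (number of comparisons = C(groups, 2)); categorical
    variables get counts/percentages and a chi-square test. Groups with
    fewer than 2 members are excluded with a warning.
    """
    group_cols = [group] if isinstance(group, str) else list(group)
    grouped = data.groupby(group_cols, sort=True)
    sizes = grouped.size()
    small = sizes[sizes < 2]
    if len(small):
        warnings.warn(f"excluding groups with n < 2: {list(small.index)}",
                      stacklevel=2)
        keep = sizes[sizes >= 2].index
        mask = data.set_index(group_cols).index.isin(keep)
        data = data[mask]
        grouped = data.groupby(group_cols, sort=True)
    keys = list(grouped.groups)
    ncomp = max(1, len(keys) * (len(keys) - 1) // 2)

    rows = []
    for var in variables:
        if var in categorical:
            tab = pd.crosstab(data[group_cols[0]] if len(group_cols) == 1
                              else [data[c] for c in group_cols], data[var])
            chi2, p = stats.chi2_contingency(tab)[:2] if tab.size > 1 else (np.nan, np.nan)
            for key in keys:
                sub = _group(grouped, key)[var]
                top = sub.value_counts().idxmax()
                rows.append({"variable": var, "group": key, "n": len(sub),
                             "mean": np.nan, "sd": np.nan,
                             "count_top": f"{top}:{(sub == top).sum()}",
                             "statistic": chi2, "pvalue": p, "test": "chi2"})
        else:
            samples = [_group(grouped, k)[var].dropna().to_numpy()
                       for k in keys]
            if all(len(s) > 1 for s in samples) and len(samples) > 1:
                fstat, p = stats.f_oneway(*samples)
            else:
                fstat, p = np.nan, np.nan
            for key, s in zip(keys, samples):
                rows.append({"variable": var, "group": key, "n": len(s),
                             "mean": float(np.mean(s)),
                             "sd": float(np.std(s, ddof=1)),
                             "count_top": "", "statistic": fstat,
                             "pvalue": p, "test": "anova"})
    summary = pd.DataFrame(rows)

    pair_rows = []
    for var in variables:
        if var in categorical:
            continue
        for a, b in itertools.combinations(keys, 2):
            xa = _group(grouped, a)[var].dropna()
            xb = _group(grouped, b)[var].dropna()
            if len(xa) > 1 and len(xb) > 1:
                _, p = stats.ttest_ind(xa, xb, equal_var=True)
                p_adj = min(1.0, p * ncomp)
            else:
                p_adj = np.nan
            pair_rows.append({"variable": var, "group_a": a, "group_b": b,
                              "p_bonferroni": p_adj})
    return summary, pd.DataFrame(pair_rows)


def laz_density_summary(panel: pd.DataFrame, attained: pd.DataFrame,
                        ages_mo=(6, 12, 18, 24), window_mo: float = 0.5,
                        grid=None, bw_method="scott") -> pd.DataFrame:
    """Gaussian kernel density of LAZ by attained-length quintile at
    selected ages, evaluated on a fixed z-grid.

    Records within +/- ``window_mo`` of each target age enter that age's
    curve. Returns a long table (quintile, age_mo, z, density, n); empty
    age windows are skipped with a warning. Each curve integrates to 1
    (up to the mass of the kernel tails beyond the grid, < 1e-3 here).
    """
    if grid is None:
        grid = np.linspace(-6.0, 6.0, 241)
    df = panel.merge(attained[["child_id", "quintile"]], on="child_id")
    df["age_mo"] = df["age_days"] / DAYS_PER_MONTH
    out = []
    for age in ages_mo:
        win = df[np.abs(df["age_mo"] - age) <= window_mo]
        for q, grp in win.groupby("quintile"):
            z = grp["laz"].dropna().to_numpy()
            if len(z) < 2 or np.ptp(z) == 0:
                warnings.warn(f"quintile {q} has too few LAZ values near "
                              f"{age} mo; curve omitted", stacklevel=2)
                continue
            dens = stats.gaussian_kde(z, bw_method=bw_method)(grid)
            out.append(pd.DataFrame({"quintile": q, "age_mo": age,
                                     "z": grid, "density": dens,
                                     "n": len(z)}))
        if len(win) == 0:
            warnings.warn(f"no observations within {window_mo} mo of "
                          f"{age} mo; age skipped", stacklevel=2)
    return (pd.concat(out, ignore_index=True) if out
            else pd.DataFrame(columns=["quintile", "age_mo", "z",
                                       "density", "n"]))
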