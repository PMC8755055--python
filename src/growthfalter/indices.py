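"""Per-observation and per-child anthropometric indices.

Implements the LMS transform for length-for-age z-scores (LAZ), the
length-for-age difference in cm (LAD), monthly length velocity scaled by
30.44 days/month, a configurable two-rule plausibility filter, and
attained length with its cohort quintiles/centiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, PanelDataError
from .reference import GrowthReference
from .units import DAYS_PER_MONTH

logger = logging.getLogger(__name__)

PANEL_COLUMNS = ["child_id", "sex", "arm", "visit_index", "date",
                 "age_days", "length_cm", "illness_reported"]

FLAG_OK = "ok"
FLAG_EXTREME_Z = "extreme_z"
FLAG_EXCESS_DECLINE = "excess_decline"


def _lms_z(x, L, M, S):
    x, L, M, S = np.broadcast_arrays(np.asarray(x, float), L, M, S)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_pow = (np.power(x / M, np.where(L == 0, 1.0, L)) - 1.0) / (
            np.where(L == 0, 1.0, L) * S)
        z_log = np.log(x / M) / S
    return np.where(L == 0, z_log, z_pow)


def compute_laz(length_cm, age_days, sex, reference: GrowthReference):
    """Length-for-age z-score via the LMS transform.

    z = ((x/M)^L - 1) / (L*S) for L != 0, and ln(x/M)/S for L = 0, with
    (L, M, S) interpolated at ``age_days`` for the given sex.
    """
    x = np.asarray(length_cm, dtype=float)
    if np.any(x <= 0):
        raise DomainError("length_cm must be positive")
    L, M, S = reference.lms(sex, age_days)
    z = _lms_z(x, L, M, S)
    return float(z) if np.ndim(length_cm) == 0 else z


def laz_to_length(z, age_days, sex, reference: GrowthReference):
    """Analytic inverse of :func:`compute_laz` (z-score back to cm)."""
    L, M, S = reference.lms(sex, age_days)
    z, L, M, S = np.broadcast_arrays(np.asarray(z, float), L, M, S)
    x_pow = M * np.power(1.0 + np.where(L == 0, 1.0, L) * S * z,
                         1.0 / np.where(L == 0, 1.0, L))
    x_log = M * np.exp(S * z)
    out = np.where(L == 0, x_log, x_pow)
    return float(out) if np.ndim(z) == 0 else out


def compute_lad(length_cm, age_days, sex, reference: GrowthReference):
    """Length-for-age difference: length minus the reference median, cm."""
    x = np.asarray(length_cm, dtype=float)
    if np.any(x <= 0):
        raise DomainError("length_cm must be positive")
    M = reference.median(sex, age_days)
    out = x - M
    return float(out) if np.ndim(length_cm) == 0 else out


def compute_velocity(panel: pd.DataFrame) -> pd.Series:
    """Monthly length velocity between consecutive retained visits.

    velocity_t = (length_t - length_{t-1}) / (age_days_t - age_days_{t-1})
    * 30.44, in cm/month; NaN at each child's first retained visit.
    Raises :class:`PanelDataError` on a non-positive age gap.
    """
    df = panel.sort_values(["child_id", "age_days"])
    gap = df.groupby("child_id")["age_days"].diff()
    bad = gap <= 0
    if bad.any():
        row = df[bad].iloc[0]
        raise PanelDataError(
            f"non-increasing age for child {row['child_id']!r} at "
            f"visit_index {row['visit_index']}")
    dlen = df.groupby("child_id")["length_cm"].diff()
    vel = dlen / gap * DAYS_PER_MONTH
    return vel.reindex(panel.index)


def derive_panel(panel: pd.DataFrame,
                 reference: GrowthReference) -> pd.DataFrame:
    """Attach laz, lad, and velocity_cm_mo columns to a cohort panel."""
    df = panel.sort_values(["child_id", "age_days"]).reset_index(drop=True)
    laz = np.empty(len(df))
    lad = np.empty(len(df))
    for sex, idx in df.groupby("sex").groups.items():
        sub = df.loc[idx]
        laz[idx] = compute_laz(sub["length_cm"].to_numpy(),
                               sub["age_days"].to_numpy(), sex, reference)
        lad[idx] = compute_lad(sub["length_cm"].to_numpy(),
                               sub["age_days"].to_numpy(), sex, reference)
    df["laz"] = laz
    df["lad"] = lad
    df["velocity_cm_mo"] = compute_velocity(df)
    return df


def flag_implausible(panel: pd.DataFrame, z_limit: float = 6.0,
                     decline_limit_cm: float = 1.5) -> pd.DataFrame:
    """Flag (never delete) biologically implausible records.

    Two rules: |LAZ| beyond ``z_limit`` (WHO-style fixed flag limit), and a
    within-child decline in measured length since the previous retained
    visit exceeding ``decline_limit_cm``. Adds a ``flag`` column with
    values ok / extreme_z / excess_decline (extreme_z wins when both fire).
    """
    df = panel.sort_values(["child_id", "age_days"]).copy()
    if "laz" not in df.columns:
        raise PanelDataError("flag_implausible requires a derived panel "
                             "with a 'laz' column")
    decline = -df.groupby("child_id")["length_cm"].diff()
    flag = np.where(np.abs(df["laz"]) > z_limit, FLAG_EXTREME_Z,
                    np.where(decline > decline_limit_cm,
                             FLAG_EXCESS_DECLINE, FLAG_OK))
    df["flag"] = flag
    return df


@dataclass
class FilterReport:
    n_records_in: int
    n_records_flagged: int
    n_children_in: int
    n_children_dropped: int
    flag_counts: dict


def filter_implausible(panel: pd.DataFrame, reference: GrowthReference,
                       z_limit: float = 6.0, decline_limit_cm: float = 1.5,
                       min_visits: int = 20):
    """Flag-then-filter: remove flagged records, re-derive velocities,
    drop children left with fewer than ``min_visits`` records.

    Returns ``(clean_derived_panel, FilterReport)``. Removing a record can
    itself unmask a new excess decline, so flagging is iterated to a fixed
    point before the visit-count rule is applied.
    """
    df = derive_panel(panel, reference)
    n_in, kids_in = len(df), df["child_id"].nunique()
    flag_counts: dict = {}
    while True:
        df = flag_implausible(df, z_limit, decline_limit_cm)
        bad = df["flag"] != FLAG_OK
        if not bad.any():
            break
        for k, v in df.loc[bad, "flag"].value_counts().items():
            flag_counts[k] = flag_counts.get(k, 0) + int(v)
        df = df[~bad]
    counts = df.groupby("child_id").size()
    keep_kids = counts[counts >= min_visits].index
    dropped = kids_in - len(keep_kids)
    if dropped:
        logger.info("plausibility filter dropped %d children below "
                    "min_visits=%d", dropped, min_visits)
    df = df[df["child_id"].isin(keep_kids)].reset_index(drop=True)
    df["velocity_cm_mo"] = compute_velocity(df)
    report = FilterReport(n_in, sum(flag_counts.values()), kids_in,
                          dropped, flag_counts)
    return df, report


def attained_length(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-child attained length (last retained visit) with quintiles.

    Quintile 1 is the shortest fifth. Children are ranked by attained
    length with child_id as the deterministic secondary key and cut at
    ranks n/5; tied attained lengths are then assigned the lowest
    provisional quintile in their tie group, so equal lengths never land in
    different quintiles. ``centile`` is the average percentile rank.
    """
    if len(panel) == 0:
        raise PanelDataError("empty panel: no children to summarize")
    df = panel.sort_values(["child_id", "age_days"])
    last = df.groupby("child_id").tail(1)
    out = pd.DataFrame({
        "child_id": last["child_id"].to_numpy(),
        "attained_length_cm": last["length_cm"].to_numpy(),
        "attained_age_mo": last["age_days"].to_numpy() / DAYS_PER_MONTH,
    }).sort_values(["attained_length_cm", "child_id"]).reset_index(drop=True)
    n = len(out)
    prov = np.arange(n) * 5 // n + 1
    quint = pd.Series(prov).groupby(out["attained_length_cm"]).transform("min")
    out["quintile"] = quint.to_numpy()
    out["centile"] = (out["attained_length_cm"]
                      .rank(method="average", pct=True) * 100.0)
    return out.sort_values("child_id").reset_index(drop=True)
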