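"""Concentric-ring use of kill sites by coyotes.

Each kill site is surrounded by 10 concentric annuli with outer radii
100-1000 m.  For the 14 days before and after the first lion fix at the
kill, every (kill, ring, day) cell becomes a binary use record: used if
at least one coyote fix fell in that annulus on that day.  Kills with no
coyote fix inside 1000 m during a window are excluded from that window's
model.  The pre- and post-kill probability-of-use models are binomial
penalized additive models with smooths of day and ring distance, a
fix-rate-adjusted local-activity count, offsets for log ring area and
log inverse fix rate, and a random intercept per kill; the post model
additionally carries a lion-active indicator that is subjected to
backwards AIC elimination.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .smooth import GamFit, SmoothSpec, backwards_aic, fit_pgam

logger = logging.getLogger(__name__)

N_RINGS = 10
RING_WIDTH_M = 100.0
WINDOW_DAYS = 14
LOCAL_RADIUS_M = 2500.0


def ring_areas_m2() -> np.ndarray:
    """Exact annulus areas for rings 1..10; they sum to the 1-km disc."""
    outer = RING_WIDTH_M * np.arange(1, N_RINGS + 1)
    inner = RING_WIDTH_M * np.arange(0, N_RINGS)
    return np.pi * (outer**2 - inner**2)


def _coyote_near(kill_row, coyote_fixes, which: str) -> bool:
    t0 = kill_row["t_first"]
    t = pd.DatetimeIndex(coyote_fixes["t"])
    if which == "pre":
        mask = (t >= t0 - pd.Timedelta(days=WINDOW_DAYS)) & (t < t0)
    else:
        mask = (t >= t0) & (t < t0 + pd.Timedelta(days=WINDOW_DAYS))
    if not mask.any():
        return False
    d = np.hypot(
        coyote_fixes.loc[mask, "x"] - kill_row["x"],
        coyote_fixes.loc[mask, "y"] - kill_row["y"],
    )
    return bool((d <= N_RINGS * RING_WIDTH_M).any())  # inclusive 1000-m boundary


def eligibility_filter(
    kills: pd.DataFrame, coyote_fixes: pd.DataFrame
) -> pd.DataFrame:
    """Flag kills eligible for the pre and post models.

    A kill enters a window's model only if at least one coyote fix lies
    within the 1000-m radius during the 14 days before (after) the first
    lion fix.  Returns the kill table with ``eligible_pre`` /
    ``eligible_post`` columns.
    """
    out = kills.copy()
    out["eligible_pre"] = [
        _coyote_near(row, coyote_fixes, "pre") for _, row in kills.iterrows()
    ]
    out["eligible_post"] = [
        _coyote_near(row, coyote_fixes, "post") for _, row in kills.iterrows()
    ]
    return out


def classify_use(
    kill_row, coyote_fixes: pd.DataFrame, which: str
) -> pd.DataFrame:
    """RingUseRecords for one kill and one window ('pre' or 'post').

    Annuli are half-open upper-inclusive: ring k covers distances in
    (100(k-1), 100k]; a fix at exactly 100.0 m falls in ring 1 (a fix at
    distance 0 also counts as ring 1).  Day bins are 24-h multiples of
    the first lion fix time: post day d covers [t_first + (d-1) days,
    t_first + d days), pre day d covers the d-th day counting back.
    Exactly 10 rings x 14 days records are produced.
    """
    t0 = kill_row["t_first"]
    t = pd.DatetimeIndex(coyote_fixes["t"])
    if which == "post":
        offset_days = (t - t0).total_seconds() / 86400.0
        in_window = (offset_days >= 0) & (offset_days < WINDOW_DAYS)
        day = np.floor(offset_days[in_window]).astype(int) + 1
    else:
        offset_days = (t0 - t).total_seconds() / 86400.0
        in_window = (offset_days > 0) & (offset_days <= WINDOW_DAYS)
        day = np.floor(offset_days[in_window] - 1e-12).astype(int) + 1
    d = np.hypot(
        coyote_fixes.loc[in_window, "x"] - kill_row["x"],
        coyote_fixes.loc[in_window, "y"] - kill_row["y"],
    ).to_numpy()
    inside = d <= N_RINGS * RING_WIDTH_M
    ring = np.maximum(np.ceil(d[inside] / RING_WIDTH_M).astype(int), 1)
    day = day[inside]

    used = np.zeros((WINDOW_DAYS, N_RINGS), dtype=bool)
    for dd, rr in zip(day, ring):
        used[dd - 1, rr - 1] = True

    areas = ring_areas_m2()
    lion_last_day = (
        (kill_row["t_last"] - t0).total_seconds() / 86400.0
    )
    records = []
    for dd in range(1, WINDOW_DAYS + 1):
        for rr in range(1, N_RINGS + 1):
            records.append(
                {
                    "kill_id": kill_row["kill_id"],
                    "which": which,
                    "day": dd,
                    "ring": rr,
                    "ring_distance_m": rr * RING_WIDTH_M,
                    "used": int(used[dd - 1, rr - 1]),
                    "ring_area_m2": areas[rr - 1],
                    "lion_active": int(which == "post" and dd <= lion_last_day + 1),
                }
            )
    return pd.DataFrame(records)


def local_intensity(
    kill_row,
    coyote_fixes: pd.DataFrame,
    fix_rate: float,
    which: str,
    radius_m: float = LOCAL_RADIUS_M,
) -> float:
    """Fix-rate-adjusted coyote activity count near the kill.

    Raw count of coyote fixes within ``radius_m`` over the 14-day window,
    divided by the collar fix rate.
    """
    if fix_rate <= 0:
        raise ValueError("fix_rate must be positive")
    t0 = kill_row["t_first"]
    t = pd.DatetimeIndex(coyote_fixes["t"])
    if which == "post":
        mask = (t >= t0) & (t < t0 + pd.Timedelta(days=WINDOW_DAYS))
    else:
        mask = (t >= t0 - pd.Timedelta(days=WINDOW_DAYS)) & (t < t0)
    d = np.hypot(
        coyote_fixes.loc[mask, "x"] - kill_row["x"],
        coyote_fixes.loc[mask, "y"] - kill_row["y"],
    )
    return float(np.count_nonzero(d <= radius_m)) / fix_rate


def build_ring_records(
    kills: pd.DataFrame,
    coyote_fixes: pd.DataFrame,
    fix_rate: float = 1.0,
) -> pd.DataFrame:
    """RingUseRecords for every eligible kill and window.

    ``fix_rate`` is the obtained/expected fix fraction of the
    contributing collars (the mean across collars when several
    contribute).  Adds per-record offsets ``ln_ring_area`` and
    ``ln_inv_fix_rate`` plus the local-activity count.
    """
    flagged = eligibility_filter(kills, coyote_fixes)
    frames = []
    for _, kill in flagged.iterrows():
        for which in ("pre", "post"):
            if not kill[f"eligible_{which}"]:
                continue
            rec = classify_use(kill, coyote_fixes, which)
            rec["local_count"] = local_intensity(kill, coyote_fixes, fix_rate, which)
            rec["fix_rate"] = fix_rate
            frames.append(rec)
    if not frames:
        return pd.DataFrame(
            columns=["kill_id", "which", "day", "ring", "ring_distance_m", "used",
                     "ring_area_m2", "lion_active", "local_count", "fix_rate"]
        )
    records = pd.concat(frames, ignore_index=True)
    records["ln_ring_area"] = np.log(records["ring_area_m2"])
    records["ln_inv_fix_rate"] = np.log(1.0 / records["fix_rate"])
    return records


def fit_killsite_model(
    records: pd.DataFrame,
    which: str,
    k_day: int = 6,
    k_ring: int = 6,
    eliminate_lion_active: bool = True,
) -> tuple[GamFit, pd.DataFrame]:
    """Binomial probability-of-use model for one window.

    used ~ s(day) + s(ring distance) + local_count [+ lion_active, post]
    with offsets log(ring area) and log(1/fix rate) and a random
    intercept per kill.  In the post model the lion-active indicator is
    passed through backwards AIC elimination.  Returns (fit, elimination
    log).
    """
    rec = records[records["which"] == which].reset_index(drop=True)
    if rec["kill_id"].nunique() < 5:
        raise ValueError("need at least 5 eligible kills")
    smooths = [
        SmoothSpec("day", "cs", k=min(k_day, rec["day"].nunique())),
        SmoothSpec("ring_distance_m", "cs", k=min(k_ring, rec["ring"].nunique())),
    ]
    if rec["kill_id"].nunique() > 1:
        smooths.append(SmoothSpec("kill_id", "re"))
    linear = ["local_count"] if rec["local_count"].std() > 0 else []
    offsets = ["ln_ring_area", "ln_inv_fix_rate"]
    removable: list[str] = []
    if which == "post" and rec["lion_active"].std() > 0:
        linear = linear + ["lion_active"]
        if eliminate_lion_active:
            removable = ["lion_active"]
    if removable:
        return backwards_aic(
            rec, "used", smooths, linear, removable, offsets, family="binomial"
        )
    fit = fit_pgam(rec, "used", smooths, linear, offsets, family="binomial")
    return fit, pd.DataFrame(columns=["removed", "delta_aic"])


def predict_use_curves(
    fit: GamFit, records: pd.DataFrame, which: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Day and ring probability-of-use curves at reference conditions.

    Predictions are made at the median local count, the first ring's
    area, and fix rate 1, mirroring a single-curve presentation: the day
    curve at ring 1, the ring curve at the day of peak use.
    """
    rec = records[records["which"] == which]
    ref = {
        "local_count": float(rec["local_count"].median()),
        "lion_active": 0,
        "ln_ring_area": float(np.log(ring_areas_m2()[0])),
        "ln_inv_fix_rate": 0.0,
        "kill_id": "__population__",  # unseen level -> population-level prediction
    }
    days = pd.DataFrame({"day": np.arange(1, WINDOW_DAYS + 1, dtype=float)})
    days["ring_distance_m"] = RING_WIDTH_M
    for k, v in ref.items():
        days[k] = v
    day_curve = pd.concat(
        [days[["day"]], fit.predict_with_ci(days)], axis=1
    )
    peak_day = float(day_curve.loc[day_curve["fit"].idxmax(), "day"])
    rings = pd.DataFrame(
        {"ring_distance_m": RING_WIDTH_M * np.arange(1, N_RINGS + 1, dtype=float)}
    )
    rings["day"] = peak_day
    for k, v in ref.items():
        rings[k] = v
    ring_curve = pd.concat(
        [rings[["ring_distance_m"]], fit.predict_with_ci(rings)], axis=1
    )
    return day_curve, ring_curve
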