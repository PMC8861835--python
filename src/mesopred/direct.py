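"""Direct risk/reward metrics: min over sources of distance x time-since.

The direct assessment of a spatiotemporally variable source (a lion's
actual locations, or its kill sites) at a query fix is the minimum, over
all *past* source events, of the product of the distance to the event
(km) and the time elapsed since it (days).  The product is
log-transformed before modelling to damp its effect at large
spatiotemporal scales.  Both factors are floored at small positive
values (1 m, 60 s) so the logarithm is defined for co-located,
simultaneous fixes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DISTANCE_FLOOR_KM = 0.001  # 1 m
DT_FLOOR_DAYS = 60.0 / 86400.0  # 60 s


@dataclass
class DirectMetric:
    """Minimum distance x time-since product over past source events."""

    value: float  # km * days
    ln_value: float
    chosen_source: int  # index into the source table
    chosen_distance_km: float
    chosen_dt_days: float


def direct_metric(
    query_x: float,
    query_y: float,
    query_t: pd.Timestamp,
    source_xy: np.ndarray,
    source_t: pd.DatetimeIndex,
) -> DirectMetric | None:
    """Evaluate the direct metric at one query fix.

    Only sources with timestamps at or before the query time count ("time
    since" runs forward from the source).  Returns ``None`` when no past
    source exists; callers drop the affected design row and log it.
    """
    source_xy = np.asarray(source_xy, dtype=float)
    if len(source_xy) == 0:
        raise ValueError("source_events must be non-empty")
    t = pd.DatetimeIndex(source_t)
    dt_days = (query_t.value - t.asi8) / 86.4e12
    past = dt_days >= 0
    if not past.any():
        return None
    dist_km = (
        np.hypot(source_xy[:, 0] - query_x, source_xy[:, 1] - query_y) / 1000.0
    )
    dist_f = np.maximum(dist_km, DISTANCE_FLOOR_KM)
    dt_f = np.maximum(dt_days, DT_FLOOR_DAYS)
    prod = np.where(past, dist_f * dt_f, np.inf)
    j = int(np.argmin(prod))
    value = float(prod[j])
    return DirectMetric(
        value=value,
        ln_value=float(np.log(value)),
        chosen_source=j,
        chosen_distance_km=float(dist_f[j]),
        chosen_dt_days=float(dt_f[j]),
    )


def direct_metric_table(
    queries: pd.DataFrame,
    source_xy: np.ndarray,
    source_t: pd.DatetimeIndex,
) -> pd.DataFrame:
    """Vectorised direct metric for a table of query fixes.

    ``queries`` needs columns ``x, y, t``.  Output columns: ``value``,
    ``ln_value``, ``chosen_distance_km``, ``chosen_dt_days``; rows with no
    past source get NaN throughout (counted in the log).
    """
    source_xy = np.asarray(source_xy, dtype=float)
    t_src = pd.DatetimeIndex(source_t).asi8  # int64 nanoseconds
    qx = queries["x"].to_numpy(dtype=float)
    qy = queries["y"].to_numpy(dtype=float)
    qt = pd.DatetimeIndex(queries["t"]).asi8
    n, m = len(queries), len(source_xy)
    out = np.full((n, 4), np.nan)
    # chunked broadcast keeps memory bounded for long tracks
    chunk = max(1, int(4_000_000 / max(m, 1)))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        dx = qx[lo:hi, None] - source_xy[None, :, 0]
        dy = qy[lo:hi, None] - source_xy[None, :, 1]
        dist = np.maximum(np.hypot(dx, dy) / 1000.0, DISTANCE_FLOOR_KM)
        # single division from integer nanoseconds keeps dt exact
        dt = (qt[lo:hi, None] - t_src[None, :]) / 86.4e12
        past = dt >= 0
        prod = np.where(past, dist * np.maximum(dt, DT_FLOOR_DAYS), np.inf)
        j = np.argmin(prod, axis=1)
        rows = np.arange(hi - lo)
        val = prod[rows, j]
        ok = np.isfinite(val)
        out[lo:hi, 0] = np.where(ok, val, np.nan)
        out[lo:hi, 1] = np.log(np.where(ok, val, 1.0))
        out[lo:hi, 1][~ok] = np.nan
        out[lo:hi, 2] = np.where(ok, dist[rows, j], np.nan)
        out[lo:hi, 3] = np.where(ok, np.maximum(dt[rows, j], DT_FLOOR_DAYS), np.nan)
    n_missing = int(np.isnan(out[:, 0]).sum())
    if n_missing:
        logger.info("direct metric undefined (no past source) at %d of %d fixes",
                    n_missing, n)
    return pd.DataFrame(
        out, columns=["value", "ln_value", "chosen_distance_km", "chosen_dt_days"],
        index=queries.index,
    )


def summarize_chosen(metrics: pd.DataFrame) -> dict[str, float]:
    """Descriptive summary of the chosen components across query fixes.

    Mirrors the reporting format of the field analysis: mean and range of
    the time-since (days) and distance (km) of the minimizing sources.
    """
    m = metrics.dropna(subset=["value"])
    if len(m) == 0:
        raise ValueError("no defined metrics to summarize")
    return {
        "mean_dt_days": float(m["chosen_dt_days"].mean()),
        "min_dt_days": float(m["chosen_dt_days"].min()),
        "max_dt_days": float(m["chosen_dt_days"].max()),
        "mean_distance_km": float(m["chosen_distance_km"].mean()),
        "min_distance_km": float(m["chosen_distance_km"].min()),
        "max_distance_km": float(m["chosen_distance_km"].max()),
        "n": int(len(m)),
    }
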