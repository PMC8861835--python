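"""Terrain and habitat covariates, standardization, and collinearity pruning.

Terrain indices follow the field-standard definitions: TRI (Riley et al.
1999) is the square root of the summed squared elevation differences
between a cell and its eight neighbours; TPI (De Reu et al. 2013) is the
cell elevation minus the mean of its neighbourhood.  Cover proportions
are evaluated inside a disc buffer (default diameter 256 m, half the mean
coyote step length).  Indirect risk/reward surfaces may be supplied as
external rasters or fitted internally from used/available points with a
tree ensemble; an ROC rule picks classification cutoffs that maximize
sensitivity at a capped false-positive rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import COVER_OPEN, COVER_SHRUB, COVER_TREE, Landscape


def compute_tri(elevation: np.ndarray) -> np.ndarray:
    """Terrain Ruggedness Index: sqrt of summed squared 8-neighbour diffs.

    Edge cells use only their available neighbours.
    """
    elev = np.asarray(elevation, dtype=float)
    if elev.ndim != 2 or min(elev.shape) < 3:
        raise ValueError("elevation grid must be at least 3x3")
    if not np.isfinite(elev).any():
        raise ValueError("elevation grid is entirely missing")
    out = np.zeros_like(elev)
    ny, nx = elev.shape
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.full_like(elev, np.nan)
            r0, r1 = max(dr, 0), ny + min(dr, 0)
            c0, c1 = max(dc, 0), nx + min(dc, 0)
            shifted[r0:r1, c0:c1] = elev[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
            diff = np.where(np.isnan(shifted), 0.0, (elev - shifted) ** 2)
            out += diff
    return np.sqrt(out)


def compute_tpi(elevation: np.ndarray, window_cells: int = 3) -> np.ndarray:
    """Topographic Position Index: cell minus mean of surrounding window.

    The centre cell is excluded from the neighbourhood mean; edge cells
    use the in-grid part of the window.
    """
    elev = np.asarray(elevation, dtype=float)
    if window_cells < 3:
        raise ValueError("window must be at least 3 cells")
    if window_cells % 2 == 0:
        raise ValueError(f"window size must be odd, got {window_cells}")
    kernel = np.ones((window_cells, window_cells))
    kernel[window_cells // 2, window_cells // 2] = 0.0
    ones = np.ones_like(elev)
    ksum = ndimage.convolve(elev, kernel, mode="constant", cval=0.0)
    kcount = ndimage.convolve(ones, kernel, mode="constant", cval=0.0)
    return elev - ksum / kcount


def cover_proportions(
    landscape: Landscape,
    x: float,
    y: float,
    buffer_diameter_m: float = 256.0,
) -> dict[str, float]:
    """Proportion of open / shrub / tree cells within a disc buffer.

    Counts cells whose centre lies within ``buffer_diameter_m / 2`` of the
    point; the three proportions sum to 1.  A buffer smaller than one cell
    degenerates to the indicator of the containing cell's class.
    """
    if not bool(landscape.contains(x, y)):
        raise ValueError(f"point ({x}, {y}) is outside the landscape")
    cover = landscape.layers["cover"]
    radius = buffer_diameter_m / 2.0
    res = landscape.resolution
    ncells = int(np.ceil(radius / res)) + 1
    row0, col0 = landscape.to_rowcol(x, y)
    ny, nx = cover.shape
    r_lo, r_hi = max(row0 - ncells, 0), min(row0 + ncells + 1, ny)
    c_lo, c_hi = max(col0 - ncells, 0), min(col0 + ncells + 1, nx)
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    cx, cy = landscape.cell_center(rr, cc)
    inside = (cx - x) ** 2 + (cy - y) ** 2 <= radius**2
    if not inside.any():  # buffer smaller than one cell
        klass = cover[row0, col0]
        return {
            "open": float(klass == COVER_OPEN),
            "shrub": float(klass == COVER_SHRUB),
            "tree": float(klass == COVER_TREE),
        }
    vals = cover[rr, cc][inside]
    n = vals.size
    return {
        "open": float(np.count_nonzero(vals == COVER_OPEN)) / n,
        "shrub": float(np.count_nonzero(vals == COVER_SHRUB)) / n,
        "tree": float(np.count_nonzero(vals == COVER_TREE)) / n,
    }


@dataclass
class ScalingRecord:
    """Per-column mean and standard deviation for inverse transforms."""

    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col in self.means:
            out[col] = (out[col] - self.means[col]) / self.sds[col]
        return out

    def invert(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col in self.means:
            out[col] = out[col] * self.sds[col] + self.means[col]
        return out


def standardize(
    table: pd.DataFrame, columns: list[str]
) -> tuple[pd.DataFrame, ScalingRecord]:
    """Centre and scale columns (mean 0, sd 1; sd with denominator n-1)."""
    record = ScalingRecord()
    out = table.copy()
    for col in columns:
        vals = table[col].to_numpy(dtype=float)
        sd = vals.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"column '{col}' has zero variance; cannot standardize")
        record.means[col] = float(vals.mean())
        record.sds[col] = float(sd)
        out[col] = (vals - record.means[col]) / sd
    return out, record


def vif_prune(
    design: pd.DataFrame, threshold: float = 3.0
) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop the highest-VIF column until all VIF < threshold.

    VIF_j = 1 / (1 - R^2_j) from regressing column j (plus intercept) on
    the remaining columns.  Perfectly collinear columns get infinite VIF
    and go first; ties break toward the earlier column in table order.
    Returns (retained column names, removal log with columns
    ``removed, vif, iteration``).
    """
    cols = list(design.columns)
    if len(cols) < 2:
        raise ValueError("need at least two columns for VIF pruning")
    if len(design) <= len(cols):
        raise ValueError("need more rows than columns for VIF pruning")
    log_rows = []
    iteration = 0
    while len(cols) >= 2:
        vifs = {}
        X = design[cols].to_numpy(dtype=float)
        for j, col in enumerate(cols):
            yj = X[:, j]
            others = np.column_stack(
                [np.ones(len(X))] + [X[:, k] for k in range(len(cols)) if k != j]
            )
            coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
            resid = yj - others @ coef
            ss_tot = ((yj - yj.mean()) ** 2).sum()
            ss_res = (resid**2).sum()
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
            vifs[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        worst = max(cols, key=lambda c: vifs[c])  # ties -> first in order (max is stable)
        if vifs[worst] < threshold:
            break
        iteration += 1
        log_rows.append({"removed": worst, "vif": vifs[worst], "iteration": iteration})
        cols.remove(worst)
    return cols, pd.DataFrame(log_rows, columns=["removed", "vif", "iteration"])


@dataclass
class OccurrenceSurface:
    """Relative probability-of-use grid in [0, 1] plus provenance."""

    grid: np.ndarray
    provenance: str  # 'external raster' | 'internal classifier'

    def __post_init__(self) -> None:
        if np.nanmin(self.grid) < 0 or np.nanmax(self.grid) > 1:
            raise ValueError("occurrence surface values must lie in [0, 1]")


def fit_occurrence_surface(
    used_xy: np.ndarray,
    available_xy: np.ndarray,
    landscape: Landscape,
    seed: int = 0,
    layer_names: list[str] | None = None,
    n_estimators: int = 100,
) -> OccurrenceSurface:
    """Fit a used/available tree-ensemble classifier over the landscape.

    A stand-in for externally supplied occurrence rasters: a random forest
    on the landscape covariate stack, predicted per cell and min-max
    rescaled to [0, 1].
    """
    from sklearn.ensemble import RandomForestClassifier

    used_xy = np.asarray(used_xy, dtype=float)
    available_xy = np.asarray(available_xy, dtype=float)
    if len(used_xy) < 20 or len(available_xy) < 20:
        raise ValueError("need at least 20 used and 20 available points")
    if layer_names is None:
        layer_names = [
            n for n in landscape.layers
            if n not in ("lion_surface", "kill_surface")
        ]

    def covar(xy):
        return np.column_stack(
            [landscape.sample(n, xy[:, 0], xy[:, 1]) for n in layer_names]
        )

    X = np.vstack([covar(used_xy), covar(available_xy)])
    y = np.r_[np.ones(len(used_xy)), np.zeros(len(available_xy))]
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate classes")
    clf = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, min_samples_leaf=5, n_jobs=1
    )
    clf.fit(X, y)

    ny, nx = landscape.shape
    rr, cc = np.mgrid[0:ny, 0:nx]
    gx, gy = landscape.cell_center(rr.ravel(), cc.ravel())
    Xgrid = np.column_stack(
        [landscape.sample(n, gx, gy) for n in layer_names]
    )
    p = clf.predict_proba(Xgrid)[:, 1].reshape(ny, nx)
    lo, hi = p.min(), p.max()
    grid = (p - lo) / (hi - lo) if hi > lo else np.full_like(p, 0.5)
    return OccurrenceSurface(grid=grid, provenance="internal classifier")


def roc_cutoff(scores, labels, max_fpr: float = 0.05) -> float:
    """Score threshold maximizing sensitivity subject to FPR <= max_fpr.

    Candidate thresholds are the observed scores (classification rule:
    positive iff score >= threshold).  Ties in sensitivity break toward
    the *lower* threshold so future classifications stay sensitive.  If no
    threshold satisfies the FPR cap, returns a value above the maximum
    score (classifying nothing positive) with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    best_thr, best_sens = None, -1.0
    for thr in np.unique(scores):
        pred = scores >= thr
        fpr = np.count_nonzero(pred & ~labels) / n_neg
        if fpr > max_fpr:
            continue
        sens = np.count_nonzero(pred & labels) / n_pos
        if sens > best_sens or (sens == best_sens and (best_thr is None or thr < best_thr)):
            best_sens, best_thr = sens, float(thr)
    if best_thr is None:
        warnings.warn(
            f"no threshold achieves FPR <= {max_fpr}; returning above-max threshold"
        )
        return float(scores.max()) + 1.0
    return best_thr
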