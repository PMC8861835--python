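"""Integrated step-selection functions with cluster-robust inference.

An iSSF compares each observed hourly movement step with matched
available steps drawn from an availability distribution (gamma step
lengths, uniform turning angles) and estimates selection with
conditional logistic regression: one stratum per observed step, the
conditional likelihood

    Q(beta) = sum_s [ eta_{s,obs} - ln sum_j exp(eta_{s,j}) ],

maximised by Newton iterations.  Standard errors come from a sandwich
estimator with scores summed within animal (the cluster), and candidate
models are ranked by the quasi-likelihood under independence criterion
QIC = -2 Q + 2 trace(A V_r) where A is the naive information and V_r the
robust covariance (Pan 2001).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .covariates import ScalingRecord, compute_tpi, compute_tri, standardize
from .direct import direct_metric_table
from .grids import Landscape, standardized_layer

logger = logging.getLogger(__name__)

N_AVAILABLE = 10
STEP_LENGTH_FLOOR_M = 0.1  # keeps ln(step length) finite for stationary fixes

#: Habitat covariates of the base model (plus the two movement terms).
BASE_HABITAT = [
    "dist_road", "dist_aspen", "dist_forest", "elevation", "tpi", "tri",
    "shrub_height", "bare_ground", "herbaceous", "sage_height",
]
MOVEMENT_TERMS = ["step_length", "ln_step_length"]

_LAYER_FOR_COLUMN = {
    "dist_road": "distance_to_road",
    "dist_aspen": "distance_to_aspen",
    "dist_forest": "distance_to_forest",
    "elevation": "elevation",
    "shrub_height": "shrub_height",
    "bare_ground": "bare_ground",
    "herbaceous": "herbaceous",
    "sage_height": "sage_height",
}


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Step construction
# ---------------------------------------------------------------------------

def build_steps(
    track, interval_h: float = 1.0, tolerance_min: float = 5.0
) -> pd.DataFrame:
    """Observed steps from a track on a nominal fix schedule.

    A step joins two consecutive fixes whose gap matches the nominal
    interval within tolerance; turning angle needs the preceding step's
    bearing, so the first step of every contiguous burst yields no
    stratum.  Returns one row per usable observed step with columns
    ``coyote_id, t0, t1, x0, y0, x1, y1, length, bearing, prev_bearing,
    turn_angle``.
    """
    fixes = track.fixes if hasattr(track, "fixes") else track
    fixes = fixes.sort_values("t").reset_index(drop=True)
    if len(fixes) < 3:
        logger.warning("track has fewer than 3 fixes; no steps built")
        return _empty_steps()
    t = pd.DatetimeIndex(fixes["t"])
    gap_h = np.diff(t.asi8) / 3.6e12
    good = np.abs(gap_h - interval_h) <= tolerance_min / 60.0

    x = fixes["x"].to_numpy()
    y = fixes["y"].to_numpy()
    rows = []
    prev_good = False
    prev_bearing = np.nan
    for i, ok in enumerate(good):
        if not ok:
            prev_good = False
            continue
        dx, dy = x[i + 1] - x[i], y[i + 1] - y[i]
        length = float(np.hypot(dx, dy))
        bearing = float(np.arctan2(dy, dx)) if length > 0 else prev_bearing
        if prev_good:  # has a preceding step -> turn angle defined
            turn = _wrap_angle(bearing - prev_bearing) if length > 0 else 0.0
            rows.append(
                {
                    "coyote_id": fixes["animal_id"].iloc[i],
                    "t0": t[i], "t1": t[i + 1],
                    "x0": x[i], "y0": y[i], "x1": x[i + 1], "y1": y[i + 1],
                    "length": length,
                    "bearing": bearing,
                    "prev_bearing": prev_bearing,
                    "turn_angle": turn,
                }
            )
        prev_good = True
        prev_bearing = bearing if np.isfinite(bearing) else prev_bearing
    if not rows:
        logger.warning("no contiguous hourly triples; no steps built")
        return _empty_steps()
    return pd.DataFrame(rows)


def _empty_steps() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["coyote_id", "t0", "t1", "x0", "y0", "x1", "y1",
                 "length", "bearing", "prev_bearing", "turn_angle"]
    )


def _wrap_angle(a: float) -> float:
    """Wrap to (-pi, pi]."""
    a = (a + np.pi) % (2 * np.pi) - np.pi
    return np.pi if a == -np.pi else a


def sample_available(
    rng: np.random.Generator,
    prev_bearing: float,
    gamma_shape: float,
    gamma_scale: float,
    n: int = N_AVAILABLE,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n available (length, turn angle) pairs.

    Lengths are gamma; turn angles uniform(-pi, pi] relative to the
    previous observed bearing.  Returns (lengths, absolute bearings are
    ``prev_bearing + angles``) as (lengths, turn_angles).
    """
    if gamma_shape <= 0 or gamma_scale <= 0:
        raise ValueError("gamma parameters must be positive")
    lengths = rng.gamma(gamma_shape, gamma_scale, size=n)
    angles = rng.uniform(-np.pi, np.pi, size=n)
    return lengths, angles


def fit_gamma_lengths(lengths) -> tuple[float, float]:
    """Gamma (shape, scale) MLE of observed step lengths, location fixed at 0.

    The availability distribution is parameterized from the observed
    steps; sampling available lengths from anything else biases the
    movement terms and lets spatial covariates absorb the residual.
    """
    from scipy import stats as _stats

    lengths = np.maximum(np.asarray(lengths, dtype=float), STEP_LENGTH_FLOOR_M)
    shape, _, scale = _stats.gamma.fit(lengths, floc=0)
    return float(shape), float(scale)


def build_design(
    observed_steps: pd.DataFrame,
    gamma_shape: float,
    gamma_scale: float,
    n_available: int = N_AVAILABLE,
    seed: int = 0,
    landscape: Landscape | None = None,
) -> pd.DataFrame:
    """Expand observed steps into strata of 1 observed + n available rows.

    Output columns: ``stratum, case, coyote_id, t0, t1, x0, y0, x1, y1,
    step_length, ln_step_length, turn_angle, cos_turn_angle``.  Available
    endpoints are placed relative to the step's start fix and the
    previous observed bearing.  When a ``landscape`` is given, available
    draws landing outside it are redrawn (the availability distribution
    is truncated to the study area, matching what the animal could do).
    """
    rng = np.random.default_rng(seed)
    frames = []
    for s, (_, row) in enumerate(observed_steps.iterrows()):
        lengths, angles = sample_available(
            rng, row["prev_bearing"], gamma_shape, gamma_scale, n_available
        )
        if landscape is not None:
            theta_a = row["prev_bearing"] + angles
            for _ in range(100):
                xa = row["x0"] + lengths * np.cos(theta_a)
                ya = row["y0"] + lengths * np.sin(theta_a)
                outside = ~landscape.contains(xa, ya)
                if not outside.any():
                    break
                n_out = int(outside.sum())
                lengths[outside], redraw = sample_available(
                    rng, row["prev_bearing"], gamma_shape, gamma_scale, n_out
                )
                angles[outside] = redraw
                theta_a[outside] = row["prev_bearing"] + redraw
        all_len = np.r_[row["length"], lengths]
        all_turn = np.r_[row["turn_angle"], angles]
        theta = row["prev_bearing"] + all_turn
        x1 = row["x0"] + all_len * np.cos(theta)
        y1 = row["y0"] + all_len * np.sin(theta)
        x1[0], y1[0] = row["x1"], row["y1"]  # keep the observed endpoint exact
        frames.append(
            pd.DataFrame(
                {
                    "stratum": s,
                    "case": np.r_[1, np.zeros(n_available)].astype(int),
                    "coyote_id": row["coyote_id"],
                    "t0": row["t0"], "t1": row["t1"],
                    "x0": row["x0"], "y0": row["y0"],
                    "x1": x1, "y1": y1,
                    "step_length": np.maximum(all_len, STEP_LENGTH_FLOOR_M),
                    "turn_angle": all_turn,
                }
            )
        )
    design = pd.concat(frames, ignore_index=True)
    design["ln_step_length"] = np.log(design["step_length"])
    design["cos_turn_angle"] = np.cos(design["turn_angle"])
    return design


# ---------------------------------------------------------------------------
# Covariate attachment
# ---------------------------------------------------------------------------

def attach_habitat_covariates(
    design: pd.DataFrame,
    landscape: Landscape,
    tpi_window: int = 3,
) -> pd.DataFrame:
    """Sample the base-model habitat covariates at step endpoints."""
    out = design.copy()
    elev = landscape.layers["elevation"]
    grids = {"tpi": compute_tpi(elev, tpi_window), "tri": compute_tri(elev)}
    x1 = out["x1"].to_numpy()
    y1 = out["y1"].to_numpy()
    row, col = landscape.to_rowcol(x1, y1)
    for colname, layer in _LAYER_FOR_COLUMN.items():
        out[colname] = landscape.layers[layer][row, col]
    for colname, grid in grids.items():
        out[colname] = grid[row, col]
    return out


def attach_layer_values(
    design: pd.DataFrame,
    landscape: Landscape,
    layers: list[str],
    grid_standardized: bool = True,
    prefix: str = "",
) -> pd.DataFrame:
    """Sample arbitrary landscape layers at step endpoints.

    With ``grid_standardized`` the layer is z-scored over the whole grid
    first — the same scale the track simulator applies its selection
    coefficients on, so fitted coefficients are directly comparable to
    the generative truth.
    """
    out = design.copy()
    row, col = landscape.to_rowcol(out["x1"].to_numpy(), out["y1"].to_numpy())
    for name in layers:
        grid = (
            standardized_layer(landscape, name)
            if grid_standardized
            else landscape.layers[name]
        )
        out[prefix + name] = grid[row, col]
    return out


def attach_indirect_surfaces(
    design: pd.DataFrame,
    lion_surface: np.ndarray,
    kill_surface: np.ndarray,
    landscape: Landscape,
) -> pd.DataFrame:
    """Sample indirect risk/reward occurrence surfaces at step endpoints."""
    out = design.copy()
    row, col = landscape.to_rowcol(out["x1"].to_numpy(), out["y1"].to_numpy())
    out["indirect_lion"] = np.asarray(lion_surface)[row, col]
    out["indirect_kill"] = np.asarray(kill_surface)[row, col]
    return out


def attach_direct_metrics(
    design: pd.DataFrame,
    lion_fixes: pd.DataFrame,
    kills: pd.DataFrame,
) -> pd.DataFrame:
    """Attach ln direct-lion and ln direct-kill metrics at step endpoints.

    Queries are evaluated at the step end point and end time.  Kill
    events are timestamped by the kill's first lion fix.  Strata whose
    query has no past source are dropped whole (1 observed + all
    available rows), logged.
    """
    out = design.copy()
    queries = pd.DataFrame(
        {"x": out["x1"], "y": out["y1"], "t": out["t1"]}, index=out.index
    )
    lion_tab = direct_metric_table(
        queries,
        lion_fixes[["x", "y"]].to_numpy(),
        pd.DatetimeIndex(lion_fixes["t"]),
    )
    kill_tab = direct_metric_table(
        queries,
        kills[["x", "y"]].to_numpy(),
        pd.DatetimeIndex(kills["t_first"]),
    )
    out["ln_direct_lion"] = lion_tab["ln_value"]
    out["ln_direct_kill"] = kill_tab["ln_value"]
    bad = out["ln_direct_lion"].isna() | out["ln_direct_kill"].isna()
    if bad.any():
        bad_strata = out.loc[bad, "stratum"].unique()
        logger.info("dropping %d strata with undefined direct metrics",
                    len(bad_strata))
        out = out[~out["stratum"].isin(bad_strata)].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Conditional logistic regression
# ---------------------------------------------------------------------------

@dataclass
class ClogitFit:
    """Conditional-logistic fit with naive and cluster-robust covariance."""

    params: pd.Series
    naive_cov: pd.DataFrame
    robust_cov: pd.DataFrame
    quasi_ll: float
    n_strata: int
    n_clusters: int
    n_iter: int
    columns: list[str] = field(default_factory=list)

    @property
    def K(self) -> int:
        return len(self.params)

    @property
    def se(self) -> pd.Series:
        """Cluster-robust SE; naive when only one cluster exists (a
        one-cluster sandwich is rank-deficient and collapses to zero)."""
        cov = self.robust_cov if self.n_clusters > 1 else self.naive_cov
        return pd.Series(np.sqrt(np.diag(cov)), index=self.params.index)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.se

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.zvalues)), index=self.params.index)

    def conf_int(self, alpha: float = 0.05, robust: bool = True) -> pd.DataFrame:
        cov = self.robust_cov if (robust and self.n_clusters > 1) else self.naive_cov
        se = np.sqrt(np.diag(cov))
        zcrit = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - zcrit * se, "upper": self.params + zcrit * se},
            index=self.params.index,
        )

    def summary(self) -> pd.DataFrame:
        """Coefficient table in the shape of a published iSSF summary."""
        return pd.DataFrame(
            {"beta": self.params, "se": self.se, "z": self.zvalues, "p": self.pvalues}
        )


def fit_clogit(
    design: pd.DataFrame,
    columns: list[str],
    stratum_col: str = "stratum",
    case_col: str = "case",
    cluster_col: str = "coyote_id",
    max_iter: int = 50,
    tol: float = 1e-8,
) -> ClogitFit:
    """Maximise the conditional (per-stratum multinomial) log-likelihood.

    Newton-Raphson with step-halving; the naive covariance is the inverse
    observed information and the robust covariance the sandwich with
    per-stratum scores summed within cluster.  Raises
    :class:`ConvergenceError` on separation or a singular information
    matrix, naming the offending covariate.
    """
    df = design.sort_values(stratum_col, kind="stable")
    strata_codes, _ = pd.factorize(df[stratum_col])
    case = df[case_col].to_numpy().astype(bool)
    n_strata = strata_codes.max() + 1
    counts = np.bincount(strata_codes)
    obs_per = np.bincount(strata_codes, weights=case.astype(float))
    if not np.all(obs_per == 1):
        raise ValueError("every stratum must contain exactly one observed case")
    X = df[list(columns)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        bad = [c for c in columns if not np.isfinite(df[c]).all()]
        raise ValueError(f"non-finite values in covariates: {bad}")
    k = X.shape[1]
    cluster_codes, clusters = pd.factorize(df[cluster_col])
    stratum_cluster = np.zeros(n_strata, dtype=int)
    stratum_cluster[strata_codes] = cluster_codes

    beta = np.zeros(k)
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        ll, grad, A, M, p = _clogit_core(X, beta, strata_codes, case, n_strata)
        try:
            step = np.linalg.solve(A, grad)
        except np.linalg.LinAlgError:
            worst = columns[int(np.argmax(np.abs(np.diag(A)) < 1e-10))]
            raise ConvergenceError(
                f"singular information matrix (near-constant covariate '{worst}')"
            )
        # step-halving safeguard
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = _clogit_ll(X, cand, strata_codes, case, n_strata)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        grad_norm = np.max(np.abs(grad)) / max(1.0, abs(ll))
        if np.max(np.abs(beta)) > 25:
            worst = columns[int(np.argmax(np.abs(beta)))]
            raise ConvergenceError(
                f"separation suspected: coefficient for '{worst}' diverging"
            )
        if grad_norm < tol and abs(ll_new - ll_old) < tol * max(1.0, abs(ll_new)):
            ll_old = ll_new
            break
        ll_old = ll_new
    else:
        raise ConvergenceError(f"Newton did not converge in {max_iter} iterations")

    ll, grad, A, M, p = _clogit_core(X, beta, strata_codes, case, n_strata)
    naive = np.linalg.inv(A)
    # per-stratum scores: x_obs - sum_j p_j x_j
    U = X[case] - M
    G = np.zeros((len(clusters), k))
    np.add.at(G, stratum_cluster, U)
    meat = G.T @ G
    robust = naive @ meat @ naive

    idx = pd.Index(columns)
    return ClogitFit(
        params=pd.Series(beta, index=idx),
        naive_cov=pd.DataFrame(naive, index=idx, columns=idx),
        robust_cov=pd.DataFrame(robust, index=idx, columns=idx),
        quasi_ll=float(ll),
        n_strata=int(n_strata),
        n_clusters=int(len(clusters)),
        n_iter=it,
        columns=list(columns),
    )


def _clogit_eta(X, beta, strata, n_strata):
    eta = X @ beta
    emax = np.full(n_strata, -np.inf)
    np.maximum.at(emax, strata, eta)
    ex = np.exp(eta - emax[strata])
    denom = np.zeros(n_strata)
    np.add.at(denom, strata, ex)
    return eta, emax, ex, denom


def _clogit_ll(X, beta, strata, case, n_strata):
    eta, emax, ex, denom = _clogit_eta(X, beta, strata, n_strata)
    lse = emax + np.log(denom)
    return float(eta[case].sum() - lse.sum())


def _clogit_core(X, beta, strata, case, n_strata):
    eta, emax, ex, denom = _clogit_eta(X, beta, strata, n_strata)
    lse = emax + np.log(denom)
    ll = float(eta[case].sum() - lse.sum())
    p = ex / denom[strata]
    grad = X.T @ (case.astype(float) - p)
    M = np.zeros((n_strata, X.shape[1]))
    np.add.at(M, strata, p[:, None] * X)
    A = (X * p[:, None]).T @ X - M.T @ M  # observed information
    return ll, grad, A, M, p


def qic(fit: ClogitFit) -> float:
    """Quasi-likelihood under independence criterion (Pan 2001).

    QIC = -2 Q + 2 trace(A V_r), with A the naive information (inverse of
    the naive covariance) and V_r the robust covariance.  When the robust
    and naive covariances coincide the trace term equals K and QIC
    reduces to -2 Q + 2 K.
    """
    A = np.linalg.inv(fit.naive_cov.to_numpy())
    trace = float(np.trace(A @ fit.robust_cov.to_numpy()))
    return -2.0 * fit.quasi_ll + 2.0 * trace


# ---------------------------------------------------------------------------
# Candidate model set and ranking
# ---------------------------------------------------------------------------

def build_model_set(available_columns) -> dict[str, list[str]]:
    """The five-candidate risk/reward model set.

    Base = movement terms + ten habitat covariates; the four augmented
    models add the printed combinations of direct and indirect risk and
    reward metrics.  Raises if a referenced covariate is missing.
    """
    base = MOVEMENT_TERMS + BASE_HABITAT
    specs = {
        "base": list(base),
        "ln_direct_kill + indirect_lion": base + ["ln_direct_kill", "indirect_lion"],
        "indirect_kill + indirect_lion": base + ["indirect_kill", "indirect_lion"],
        "ln_direct_kill + ln_direct_lion": base + ["ln_direct_kill", "ln_direct_lion"],
        "indirect_kill + ln_direct_lion": base + ["indirect_kill", "ln_direct_lion"],
    }
    available = set(available_columns)
    for name, cols in specs.items():
        missing = [c for c in cols if c not in available]
        if missing:
            raise ValueError(f"model '{name}' references missing covariates {missing}")
        if len(set(cols)) != len(cols):
            raise ValueError(f"model '{name}' contains duplicate covariates")
    return specs


def rank_models(fits: dict[str, ClogitFit]) -> pd.DataFrame:
    """Rank fits by QIC; columns mirror a published model-selection table."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to rank")
    strata_counts = {f.n_strata for f in fits.values()}
    if len(strata_counts) > 1:
        raise ValueError(f"fits use different strata sets: {strata_counts}")
    rows = [
        {"model": name, "quasi_ll": f.quasi_ll, "K": f.K, "qic": qic(f)}
        for name, f in fits.items()
    ]
    table = pd.DataFrame(rows)
    table["delta_qic"] = table["qic"] - table["qic"].min()
    return table.sort_values("delta_qic", kind="stable").reset_index(drop=True)
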