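"""Synthetic GPS tracks and kill sites with known ground truth.

The coyote simulator is the generative dual of the integrated
step-selection function fitted by :mod:`mesopred.issf`: at every step a
set of candidate endpoints is drawn from the availability distribution
(gamma step lengths, uniform turning angles) and one is chosen with
probability proportional to ``exp(beta . covariates)``.  Tracks simulated
with known selection coefficients therefore have recoverable coefficients
under the matching iSSF, which is what makes every downstream stage
testable without field data.

The mountain-lion simulator alternates correlated-walk travel bouts with
multi-day residencies at kill sites; kill records carry the first and
last lion fix time at the kill, the quantities the kill-site use analysis
keys on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import Landscape, standardized_layer

#: Gamma step-length distribution fitted to hourly coyote steps (metres).
COYOTE_GAMMA_SHAPE = 0.38
COYOTE_GAMMA_SCALE = 1402.57

#: Overall GPS fix success of the coyote collars.
FIX_SUCCESS = 0.898

#: Mean time lions stay active at a kill site (days).
LION_RESIDENCY_MEAN_DAYS = 4.5

#: Start of the hourly-fix season used throughout (15 May).
SEASON_START = pd.Timestamp("2019-05-15 00:00:00", tz="UTC")


@dataclass
class Track:
    """Ordered GPS fixes for one animal on a nominal fix schedule."""

    fixes: pd.DataFrame  # columns: animal_id, species, t, x, y
    interval_h: float = 1.0
    success_rate: float = 1.0

    def __post_init__(self) -> None:
        t = self.fixes["t"]
        if len(t) > 1 and not t.is_monotonic_increasing:
            raise ValueError("fix timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def animal_id(self) -> str:
        return self.fixes["animal_id"].iloc[0] if len(self.fixes) else ""


@dataclass
class ScenarioTruth:
    """Everything that determines a simulation besides the seed."""

    seed: int
    selection_betas: dict[str, float] = field(default_factory=dict)
    gamma_shape: float = COYOTE_GAMMA_SHAPE
    gamma_scale: float = COYOTE_GAMMA_SCALE
    residency_mean_days: float = LION_RESIDENCY_MEAN_DAYS
    extras: dict = field(default_factory=dict)


def _fix_frame(animal_id, species, times, xs, ys):
    return pd.DataFrame(
        {
            "animal_id": animal_id,
            "species": species,
            "t": pd.DatetimeIndex(times),
            "x": np.asarray(xs, dtype=float),
            "y": np.asarray(ys, dtype=float),
        }
    )


def sim_coyote_track(
    landscape: Landscape,
    start: tuple[float, float],
    n_steps: int,
    gamma_shape: float = COYOTE_GAMMA_SHAPE,
    gamma_scale: float = COYOTE_GAMMA_SCALE,
    selection_betas: dict[str, float] | None = None,
    interval_h: float = 1.0,
    seed: int = 0,
    n_candidates: int = 50,
    animal_id: str = "coyote_1",
    start_time: pd.Timestamp = SEASON_START,
) -> Track:
    """Simulate a habitat-selecting coyote track.

    Each step draws ``n_candidates`` endpoints from the availability
    distribution (gamma lengths, uniform turns relative to the previous
    bearing) and keeps one with probability proportional to
    ``exp(sum_l beta_l * z_l(endpoint))`` where ``z_l`` is the grid-wide
    z-score of landscape layer ``l``.  ``selection_betas`` of ``None`` or
    all zeros gives an unbiased correlated random walk, so the empirical
    mean step length converges on ``shape * scale``.
    """
    if gamma_shape <= 0 or gamma_scale <= 0:
        raise ValueError("gamma_shape and gamma_scale must be positive")
    if not bool(landscape.contains(start[0], start[1])):
        raise ValueError(f"start {start} lies outside the landscape")
    rng = np.random.default_rng(seed)
    betas = dict(selection_betas or {})
    zlayers = {name: standardized_layer(landscape, name) for name in betas}

    xs = np.empty(n_steps + 1)
    ys = np.empty(n_steps + 1)
    xs[0], ys[0] = start
    bearing = rng.uniform(-np.pi, np.pi)

    for i in range(n_steps):
        for _attempt in range(20):
            lengths = rng.gamma(gamma_shape, gamma_scale, size=n_candidates)
            turns = rng.uniform(-np.pi, np.pi, size=n_candidates)
            theta = bearing + turns
            cx = xs[i] + lengths * np.cos(theta)
            cy = ys[i] + lengths * np.sin(theta)
            inside = landscape.contains(cx, cy)
            if inside.any():
                break
        else:  # pinned against a corner: stay put this hour
            xs[i + 1], ys[i + 1] = xs[i], ys[i]
            continue
        logw = np.where(inside, 0.0, -np.inf)
        if betas:
            row, col = landscape.to_rowcol(cx, cy)
            for name, beta in betas.items():
                logw = logw + beta * zlayers[name][row, col]
        logw -= logw[inside].max()
        w = np.exp(logw)
        pick = rng.choice(n_candidates, p=w / w.sum())
        xs[i + 1], ys[i + 1] = cx[pick], cy[pick]
        if lengths[pick] > 0:
            bearing = theta[pick]

    times = start_time + pd.to_timedelta(np.arange(n_steps + 1) * interval_h, unit="h")
    return Track(
        fixes=_fix_frame(animal_id, "coyote", times, xs, ys),
        interval_h=interval_h,
    )


def sim_lion_track_and_kills(
    landscape: Landscape,
    n_days: float,
    kill_rate_per_day: float = 0.12,
    residency_mean_days: float = LION_RESIDENCY_MEAN_DAYS,
    interval_h: float = 3.0,
    seed: int = 0,
    travel_step_mean_m: float = 1500.0,
    cluster_radius_m: float = 50.0,
    bias_layer: str | None = None,
    bias_beta: float = 1.0,
    animal_id: str = "lion_1",
    start_time: pd.Timestamp = SEASON_START,
) -> tuple[Track, pd.DataFrame]:
    """Simulate a mountain-lion track alternating travel and kill residency.

    While travelling the lion takes correlated-walk steps (gamma lengths
    with mean ``travel_step_mean_m`` per fix interval), optionally biased
    toward high values of ``bias_layer``.  At each travelling fix a kill
    occurs with probability ``kill_rate_per_day * interval_h / 24``; the
    lion then stays within ``cluster_radius_m`` of the kill for an
    exponentially distributed residency with the given mean.  Kill records
    take ``t_first`` / ``t_last`` from the simulated fixes at the site.

    Returns the track and a kill table with columns
    ``kill_id, x, y, t_first, t_last, prey_large``.
    """
    if residency_mean_days <= 0:
        raise ValueError("residency_mean_days must be positive")
    rng = np.random.default_rng(seed)
    n_fixes = int(round(n_days * 24.0 / interval_h)) + 1
    p_kill = kill_rate_per_day * interval_h / 24.0
    zbias = standardized_layer(landscape, bias_layer) if bias_layer else None
    xmin, xmax, ymin, ymax = landscape.extent

    x = 0.5 * (xmin + xmax)
    y = 0.5 * (ymin + ymax)
    bearing = rng.uniform(-np.pi, np.pi)
    xs, ys = [x], [y]
    kills: list[dict] = []
    resid_end = -1  # fix index at which the current residency ends
    kill_pos = (x, y)

    for i in range(1, n_fixes):
        if i <= resid_end:  # clustered fixes at the active kill
            r = cluster_radius_m * np.sqrt(rng.uniform())
            a = rng.uniform(-np.pi, np.pi)
            x = kill_pos[0] + r * np.cos(a)
            y = kill_pos[1] + r * np.sin(a)
        else:
            for _attempt in range(50):
                length = rng.gamma(2.0, travel_step_mean_m / 2.0)
                turn = rng.normal(0.0, 0.8)
                if zbias is not None:
                    # pick among a handful of biased candidate headings
                    turns = rng.normal(0.0, 0.8, size=8)
                    thetas = bearing + turns
                    cx = x + length * np.cos(thetas)
                    cy = y + length * np.sin(thetas)
                    ok = landscape.contains(cx, cy)
                    if not ok.any():
                        bearing = rng.uniform(-np.pi, np.pi)
                        continue
                    row, col = landscape.to_rowcol(cx, cy)
                    logw = np.where(ok, bias_beta * zbias[row, col], -np.inf)
                    logw -= logw[ok].max()
                    w = np.exp(logw)
                    pick = rng.choice(8, p=w / w.sum())
                    nx_, ny_ = cx[pick], cy[pick]
                    theta = thetas[pick]
                else:
                    theta = bearing + turn
                    nx_ = x + length * np.cos(theta)
                    ny_ = y + length * np.sin(theta)
                    if not bool(landscape.contains(nx_, ny_)):
                        bearing = rng.uniform(-np.pi, np.pi)
                        continue
                x, y, bearing = float(nx_), float(ny_), float(theta)
                break
            if rng.uniform() < p_kill:
                kill_pos = (x, y)
                duration_days = rng.exponential(residency_mean_days)
                n_resid = int(duration_days * 24.0 / interval_h)
                resid_end = i + n_resid
                kills.append(
                    {
                        "x": x,
                        "y": y,
                        "i_first": i,
                        "i_last": min(resid_end, n_fixes - 1),
                        "prey_large": bool(rng.uniform() < 0.8),
                    }
                )
        xs.append(x)
        ys.append(y)

    times = start_time + pd.to_timedelta(np.arange(n_fixes) * interval_h, unit="h")
    track = Track(
        fixes=_fix_frame(animal_id, "lion", times, xs, ys),
        interval_h=interval_h,
    )
    kill_df = pd.DataFrame(
        {
            "kill_id": [f"{animal_id}_k{j}" for j in range(len(kills))],
            "x": [k["x"] for k in kills],
            "y": [k["y"] for k in kills],
            "t_first": [times[k["i_first"]] for k in kills],
            "t_last": [times[k["i_last"]] for k in kills],
            "prey_large": [k["prey_large"] for k in kills],
        }
    )
    return track, kill_df


def apply_fix_failure(track: Track, success_rate: float, seed: int = 0) -> Track:
    """Drop each scheduled fix independently with probability 1 - success_rate."""
    if not 0 < success_rate <= 1:
        raise ValueError("success_rate must be in (0, 1]")
    if success_rate == 1.0 or len(track) == 0:
        return Track(track.fixes.copy(), track.interval_h, success_rate)
    rng = np.random.default_rng(seed)
    keep = rng.uniform(size=len(track)) < success_rate
    return Track(
        fixes=track.fixes.loc[keep].reset_index(drop=True),
        interval_h=track.interval_h,
        success_rate=success_rate,
    )


# ---------------------------------------------------------------------------
# Full study scenarios
# ---------------------------------------------------------------------------

#: Default truth for the risk-reward scenario: avoidance of the lion
#: occurrence surface, mild attraction to the kill-site surface, and two
#: habitat effects; no response to the direct (actual-location) metrics.
DEFAULT_SELECTION_BETAS = {
    "lion_surface": -0.5,
    "kill_surface": 0.3,
    "herbaceous": 0.15,
    "bare_ground": -0.2,
}


@dataclass
class Scenario:
    """A complete simulated study: landscape, tracks, kills, truth."""

    landscape: Landscape
    coyote_tracks: list[Track]
    lion_tracks: list[Track]
    kills: pd.DataFrame
    truth: ScenarioTruth

    @property
    def coyote_fixes(self) -> pd.DataFrame:
        return pd.concat([t.fixes for t in self.coyote_tracks], ignore_index=True)

    @property
    def lion_fixes(self) -> pd.DataFrame:
        return pd.concat([t.fixes for t in self.lion_tracks], ignore_index=True)


def _occurrence_truth(landscape: Landscape, seed: int, smoothness: float = 6.0) -> None:
    """Attach 'true' lion and kill occurrence surfaces as landscape layers.

    The surfaces play the role the externally modelled occurrence rasters
    play on real data.  Each mixes a mild habitat association with its
    own spatially autocorrelated latent field, so the surfaces carry
    information beyond the base habitat covariates — as an occurrence
    model trained on another species' data does.
    """
    from scipy import ndimage

    rng = np.random.default_rng(seed)

    def latent():
        f = ndimage.gaussian_filter(
            rng.standard_normal(landscape.shape), sigma=smoothness, mode="reflect"
        )
        return (f - f.mean()) / f.std()

    z = lambda name: standardized_layer(landscape, name)
    lion = 1.0 / (1.0 + np.exp(-(1.1 * latent() + 0.5 * z("elevation")
                                 - 0.3 * z("distance_to_forest"))))
    kill = 1.0 / (1.0 + np.exp(-(1.1 * latent() + 0.4 * z("shrub_height"))))
    landscape.layers["lion_surface"] = lion
    landscape.layers["kill_surface"] = kill


def make_scenario(
    seed: int,
    n_coyotes: int = 4,
    steps_per_coyote: int = 1500,
    n_lions: int = 2,
    n_days: float | None = None,
    extent: tuple[int, int] = (200, 200),
    selection_betas: dict[str, float] | None = None,
    fix_success: float = FIX_SUCCESS,
    kill_rate_per_day: float = 0.12,
    residency_mean_days: float = LION_RESIDENCY_MEAN_DAYS,
    lion_surface_bias: float | None = 1.0,
) -> Scenario:
    """Build the default synthetic study.

    Hourly coyote fixes over the 15 May - 30 Sep season with ~90% fix
    success, 3-h lion fixes with multi-day kill residencies, and habitat
    composites standing in for the externally modelled lion / kill-site
    occurrence surfaces.  Coyotes are simulated with
    :data:`DEFAULT_SELECTION_BETAS` unless overridden.
    """
    from .grids import gen_landscape

    if n_days is None:
        # lions overlap the coyote season plus a margin so late kills
        # still have a full post-kill observation window
        n_days = steps_per_coyote / 24.0 + 7.0
    rng = np.random.default_rng(seed)
    landscape = gen_landscape(int(rng.integers(2**31)), extent=extent)
    _occurrence_truth(landscape, seed)
    betas = DEFAULT_SELECTION_BETAS if selection_betas is None else selection_betas

    xmin, xmax, ymin, ymax = landscape.extent
    span_x, span_y = xmax - xmin, ymax - ymin

    coyotes = []
    for j in range(n_coyotes):
        start = (
            xmin + span_x * rng.uniform(0.3, 0.7),
            ymin + span_y * rng.uniform(0.3, 0.7),
        )
        full = sim_coyote_track(
            landscape,
            start,
            steps_per_coyote,
            selection_betas=betas,
            seed=int(rng.integers(2**31)),
            animal_id=f"coyote_{j + 1}",
        )
        coyotes.append(apply_fix_failure(full, fix_success, seed=int(rng.integers(2**31))))

    lions, kill_frames = [], []
    for j in range(n_lions):
        track, kills = sim_lion_track_and_kills(
            landscape,
            n_days=n_days,
            kill_rate_per_day=kill_rate_per_day,
            residency_mean_days=residency_mean_days,
            seed=int(rng.integers(2**31)),
            bias_layer="lion_surface" if lion_surface_bias else None,
            bias_beta=lion_surface_bias or 0.0,
            animal_id=f"lion_{j + 1}",
        )
        lions.append(track)
        kill_frames.append(kills)
    non_empty = [k for k in kill_frames if len(k)]
    kills = (
        pd.concat(non_empty, ignore_index=True) if non_empty else kill_frames[0]
    )

    truth = ScenarioTruth(
        seed=seed,
        selection_betas=dict(betas),
        residency_mean_days=residency_mean_days,
        extras={"n_coyotes": n_coyotes, "steps_per_coyote": steps_per_coyote,
                "kill_rate_per_day": kill_rate_per_day, "fix_success": fix_success,
                "lion_surface_bias": lion_surface_bias},
    )
    return Scenario(landscape, coyotes, lions, kills, truth)


# ---------------------------------------------------------------------------
# Fix-table CSV round trip
# ---------------------------------------------------------------------------

def fixes_to_csv(fixes: pd.DataFrame, path) -> None:
    out = fixes.copy()
    out["iso8601_utc"] = out["t"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out[["animal_id", "species", "iso8601_utc", "x", "y"]].to_csv(path, index=False)


def fixes_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["t"] = pd.to_datetime(df["iso8601_utc"], utc=True)
    return df[["animal_id", "species", "t", "x", "y"]]


def kills_to_csv(kills: pd.DataFrame, path) -> None:
    out = kills.copy()
    for col in ("t_first", "t_last"):
        out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def kills_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("t_first", "t_last"):
        df[col] = pd.to_datetime(df[col], utc=True)
    return df
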