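"""Coyote-lion encounter detection and pre/post-encounter behaviour.

An encounter candidate is one coyote fix and one lion fix within 1 km
and 2 h of each other (both thresholds inclusive).  Consecutive
qualifying coyote fixes merge into one encounter bout; a bout ends when
the space-time criterion fails.  Encounters starting within five hours
of the previous retained encounter's end (per coyote) are excluded as
non-independent.  Around each independent encounter the module extracts
pre/post windows of hourly movement rates (for the gamma GAMM) and
builds a step-selection design with pre/post-specific step-length
distributions and time-to-encounter interactions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import issf
from .covariates import compute_tri, standardize
from .grids import Landscape
from .smooth import GamFit, SmoothSpec, fit_pgam

logger = logging.getLogger(__name__)

DIST_KM_DEFAULT = 1.0
DT_H_DEFAULT = 2.0
GAP_H_DEFAULT = 5.0

#: Gamma step-length parameters fitted separately to the pre- and
#: post-encounter observed steps, preserving existing differences in
#: movement behaviour.
PRE_GAMMA = (0.38, 1177.75)
POST_GAMMA = (0.41, 1413.39)


@dataclass
class Encounter:
    """A merged bout of qualifying coyote-lion fix pairs."""

    coyote_id: str
    lion_id: str
    t_start: pd.Timestamp
    t_end: pd.Timestamp
    n_pairs: int
    independent: bool = True

    @property
    def multi_hour(self) -> bool:
        return self.t_end > self.t_start


def detect_encounters(
    coyote_fixes: pd.DataFrame,
    lion_fixes: pd.DataFrame,
    dist_km: float = DIST_KM_DEFAULT,
    dt_h: float = DT_H_DEFAULT,
) -> pd.DataFrame:
    """All (coyote fix, lion fix) pairs within both thresholds.

    A time-sorted sweep over lion fixes bounds the candidate set per
    coyote fix; the result equals the brute-force double loop exactly.
    Returns one row per qualifying pair with the coyote fix time/location,
    the lion fix time/location, and their separation.
    """
    if len(coyote_fixes) == 0 or len(lion_fixes) == 0:
        return _empty_pairs()
    lf = lion_fixes.sort_values("t").reset_index(drop=True)
    lt = pd.DatetimeIndex(lf["t"]).asi8 / 3.6e12  # hours
    lx = lf["x"].to_numpy()
    ly = lf["y"].to_numpy()
    lid = lf["animal_id"].to_numpy()

    rows = []
    ct_all = pd.DatetimeIndex(coyote_fixes["t"])
    ct_h = ct_all.asi8 / 3.6e12
    cx = coyote_fixes["x"].to_numpy()
    cy = coyote_fixes["y"].to_numpy()
    cid = coyote_fixes["animal_id"].to_numpy()
    dist_m = dist_km * 1000.0
    for i in range(len(coyote_fixes)):
        lo = np.searchsorted(lt, ct_h[i] - dt_h, side="left")
        hi = np.searchsorted(lt, ct_h[i] + dt_h, side="right")
        if lo >= hi:
            continue
        d = np.hypot(lx[lo:hi] - cx[i], ly[lo:hi] - cy[i])
        dt = np.abs(lt[lo:hi] - ct_h[i])
        ok = (d <= dist_m) & (dt <= dt_h + 1e-12)
        for j in np.flatnonzero(ok):
            rows.append(
                {
                    "coyote_id": cid[i],
                    "lion_id": lid[lo + j],
                    "t_coyote": ct_all[i],
                    "t_lion": lf["t"].iloc[lo + j],
                    "x_coyote": cx[i], "y_coyote": cy[i],
                    "x_lion": lx[lo + j], "y_lion": ly[lo + j],
                    "dist_m": float(d[j]),
                    "dt_h": float(dt[j]),
                }
            )
    return pd.DataFrame(rows) if rows else _empty_pairs()


def _empty_pairs() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["coyote_id", "lion_id", "t_coyote", "t_lion",
                 "x_coyote", "y_coyote", "x_lion", "y_lion", "dist_m", "dt_h"]
    )


def merge_bouts(
    pairs: pd.DataFrame, merge_gap_h: float = 1.0
) -> list[Encounter]:
    """Merge qualifying pairs of one coyote-lion dyad into encounter bouts.

    Qualifying coyote fix times separated by at most ``merge_gap_h``
    (the nominal fix interval) belong to the same bout; a longer gap
    between qualifying fixes ends the encounter.  ``t_start`` / ``t_end``
    are the first and last qualifying coyote fix times of the bout.
    """
    if len(pairs) == 0:
        return []
    dyads = pairs.groupby(["coyote_id", "lion_id"], sort=True)
    encounters: list[Encounter] = []
    for (cid, lid), grp in dyads:
        times = pd.DatetimeIndex(sorted(grp["t_coyote"].unique()))
        counts = grp.groupby("t_coyote").size()
        start = times[0]
        prev = times[0]
        n_pairs = int(counts.loc[times[0]])
        for t in times[1:]:
            if (t - prev).total_seconds() / 3600.0 <= merge_gap_h + 1e-12:
                n_pairs += int(counts.loc[t])
            else:
                encounters.append(Encounter(cid, lid, start, prev, n_pairs))
                start = t
                n_pairs = int(counts.loc[t])
            prev = t
        encounters.append(Encounter(cid, lid, start, prev, n_pairs))
    encounters.sort(key=lambda e: (str(e.coyote_id), e.t_start, str(e.lion_id)))
    return encounters


def filter_independent(
    encounters: list[Encounter], gap_h: float = GAP_H_DEFAULT
) -> list[Encounter]:
    """Drop encounters starting within ``gap_h`` of the previous retained
    encounter's end for the same coyote (strict inequality: exactly
    ``gap_h`` later is retained).  Encounters are pooled per coyote
    across lions, and the ``independent`` flag is set on every input.
    """
    by_coyote: dict[str, list[Encounter]] = {}
    for e in sorted(encounters, key=lambda e: (str(e.coyote_id), e.t_start)):
        by_coyote.setdefault(str(e.coyote_id), []).append(e)
    kept: list[Encounter] = []
    for cid, encs in by_coyote.items():
        last_end = None
        for e in encs:
            if last_end is not None and (
                (e.t_start - last_end).total_seconds() / 3600.0 < gap_h
            ):
                e.independent = False
                continue
            e.independent = True
            kept.append(e)
            last_end = e.t_end
    kept.sort(key=lambda e: (str(e.coyote_id), e.t_start))
    return kept


def encounters_to_frame(encounters: list[Encounter]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "coyote_id": e.coyote_id,
                "lion_id": e.lion_id,
                "t_start": e.t_start,
                "t_end": e.t_end,
                "n_pairs": e.n_pairs,
                "multi_hour": e.multi_hour,
                "independent": e.independent,
            }
            for e in encounters
        ],
        columns=["coyote_id", "lion_id", "t_start", "t_end",
                 "n_pairs", "multi_hour", "independent"],
    )


# ---------------------------------------------------------------------------
# Movement-rate records and model
# ---------------------------------------------------------------------------

def extract_windows(
    coyote_fixes: pd.DataFrame,
    encounter: Encounter,
    encounter_id: int,
    window_h: float = 5.0,
    interval_h: float = 1.0,
    tolerance_min: float = 5.0,
) -> pd.DataFrame:
    """Hourly movement-rate records in the pre/post encounter windows.

    Only behaviour strictly before ``t_start`` and strictly after
    ``t_end`` is evaluated; fixes inside the bout are excluded.  A rate
    record is the displacement between consecutive fixes one nominal
    interval apart, timestamped at the later fix.  ``time_to_encounter``
    is negative pre (hours before ``t_start``) and positive post (hours
    after ``t_end``).
    """
    fx = coyote_fixes[coyote_fixes["animal_id"] == encounter.coyote_id]
    rates = _hourly_rates(fx, interval_h, tolerance_min)
    out = _window_records(rates, encounter, encounter_id, window_h)
    if len(out) == 0:
        logger.info("no fixes in the ±%gh window of encounter %s", window_h,
                    encounter_id)
    return out


def _hourly_rates(
    fixes: pd.DataFrame, interval_h: float = 1.0, tolerance_min: float = 5.0
) -> pd.DataFrame:
    """Consecutive-fix movement rates (m/h) for one animal's fixes."""
    fx = fixes.sort_values("t").reset_index(drop=True)
    t = pd.DatetimeIndex(fx["t"])
    if len(fx) < 2:
        return pd.DataFrame(columns=["t", "hour_of_day", "rate"])
    gap_h = np.diff(t.asi8) / 3.6e12
    ok = np.abs(gap_h - interval_h) <= tolerance_min / 60.0
    d = np.hypot(np.diff(fx["x"].to_numpy()), np.diff(fx["y"].to_numpy()))
    tt = t[1:][ok]
    return pd.DataFrame(
        {
            "t": tt,
            "hour_of_day": tt.hour + tt.minute / 60.0,
            "rate": d[ok] / gap_h[ok],
        }
    )


def _window_records(
    rates: pd.DataFrame, encounter: Encounter, encounter_id: int, window_h: float
) -> pd.DataFrame:
    cols = ["coyote_id", "encounter_id", "time_to_encounter", "hour_of_day", "rate"]
    if len(rates) == 0:
        return pd.DataFrame(columns=cols)
    t = pd.DatetimeIndex(rates["t"])
    pre_h = (t - encounter.t_start).total_seconds() / 3600.0
    post_h = (t - encounter.t_end).total_seconds() / 3600.0
    pre = (pre_h >= -window_h) & (pre_h < 0)
    post = (post_h > 0) & (post_h <= window_h)
    tte = np.where(pre, pre_h, post_h)
    sel = pre | post
    if not sel.any():
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(
        {
            "coyote_id": encounter.coyote_id,
            "encounter_id": encounter_id,
            "time_to_encounter": tte[sel],
            "hour_of_day": rates.loc[sel, "hour_of_day"].to_numpy(),
            "rate": rates.loc[sel, "rate"].to_numpy(),
        }
    )


def build_rate_records(
    coyote_fixes: pd.DataFrame,
    encounters: list[Encounter],
    window_h: float = 5.0,
) -> pd.DataFrame:
    rates_by_coyote = {
        cid: _hourly_rates(grp) for cid, grp in coyote_fixes.groupby("animal_id")
    }
    frames = [
        _window_records(rates_by_coyote[e.coyote_id], e, eid, window_h)
        for eid, e in enumerate(encounters)
        if e.coyote_id in rates_by_coyote
    ]
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(
            columns=["coyote_id", "encounter_id", "time_to_encounter",
                     "hour_of_day", "rate"]
        )
    return pd.concat(frames, ignore_index=True)


def fit_rate_model(rate_records: pd.DataFrame, k_tte: int = 8) -> GamFit:
    """Gamma GAMM of hourly movement rate around encounters.

    rate ~ s(time_to_encounter) + s_cyclic(hour_of_day, 24 h) with nested
    random intercepts for coyote and encounter.  Non-positive rates are
    floored at 1 m/h (gamma support), logged.
    """
    rec = rate_records.copy()
    if rec["time_to_encounter"].nunique() < 5:
        raise ValueError("need at least 5 distinct time-to-encounter values")
    n_floor = int((rec["rate"] <= 0).sum())
    if n_floor:
        logger.info("flooring %d non-positive rates at 1 m/h", n_floor)
        rec.loc[rec["rate"] <= 0, "rate"] = 1.0
    k_tte = min(k_tte, rec["time_to_encounter"].nunique())
    k_hour = min(8, rec["hour_of_day"].nunique())
    smooths = [SmoothSpec("time_to_encounter", "cs", k=k_tte)]
    if k_hour >= 4:
        smooths.append(SmoothSpec("hour_of_day", "cc", k=k_hour, period=24.0))
    for g in ("coyote_id", "encounter_id"):
        if rec[g].nunique() > 1:
            smooths.append(SmoothSpec(g, "re"))
    return fit_pgam(rec, "rate", smooths, family="gamma")


# ---------------------------------------------------------------------------
# Encounter-window step-selection design and fit
# ---------------------------------------------------------------------------

ENCOUNTER_MAIN_EFFECTS = ["cos_turn_angle", "shrub", "tree", "dist_lion", "tri"]


def _cover_proportion_grids(landscape: Landscape, buffer_diameter_m: float):
    """Per-cell shrub and tree proportions within the disc buffer."""
    from scipy import ndimage

    cover = landscape.layers["cover"]
    radius = buffer_diameter_m / 2.0
    ncells = int(np.ceil(radius / landscape.resolution)) + 1
    rr, cc = np.mgrid[-ncells:ncells + 1, -ncells:ncells + 1]
    kernel = (
        (rr * landscape.resolution) ** 2 + (cc * landscape.resolution) ** 2
        <= radius**2
    ).astype(float)
    if kernel.sum() == 0:
        kernel[ncells, ncells] = 1.0
    out = []
    for klass in (1, 2):  # shrub, tree
        ind = (cover == klass).astype(float)
        num = ndimage.convolve(ind, kernel, mode="constant", cval=0.0)
        den = ndimage.convolve(np.ones_like(ind), kernel, mode="constant", cval=0.0)
        out.append(num / den)
    return out[0], out[1]


def build_encounter_issf(
    coyote_fixes: pd.DataFrame,
    lion_fixes: pd.DataFrame,
    encounters: list[Encounter],
    landscape: Landscape,
    window_h: float = 10.0,
    n_available: int = issf.N_AVAILABLE,
    seed: int = 0,
    buffer_diameter_m: float = 256.0,
    pre_gamma: tuple[float, float] = PRE_GAMMA,
    post_gamma: tuple[float, float] = POST_GAMMA,
    estimate_gamma: bool = True,
) -> tuple[pd.DataFrame, issf.ClogitFit]:
    """Design and conditional-logistic fit for pre/post-encounter selection.

    Steps in the 10 h before/after each independent encounter are paired
    with available steps whose lengths come from the pre- or
    post-encounter gamma distribution respectively — parameterized from
    the observed window steps when ``estimate_gamma`` (keeping
    availability matched to the animals at hand), otherwise from the
    supplied ``pre_gamma`` / ``post_gamma``.  Covariates at step
    endpoints: cos(turn angle), shrub and tree cover proportions in a
    256-m-diameter buffer, distance to the encounter lion's most recent
    fix, and TRI; each main effect (except the two step-length terms) is
    also interacted with signed time-to-encounter.  Main effects and
    time-to-encounter are standardized before interaction.
    """
    rng = np.random.default_rng(seed)
    tri_grid = compute_tri(landscape.layers["elevation"])
    lion_by_id = {
        lid: grp.sort_values("t").reset_index(drop=True)
        for lid, grp in lion_fixes.groupby("animal_id")
    }

    phase_steps: list[tuple[int, Encounter, str, pd.DataFrame]] = []
    for eid, enc in enumerate(encounters):
        fx = coyote_fixes[coyote_fixes["animal_id"] == enc.coyote_id]
        t = pd.DatetimeIndex(fx["t"])
        pre_mask = (t >= enc.t_start - pd.Timedelta(hours=window_h)) & (t < enc.t_start)
        post_mask = (t > enc.t_end) & (t <= enc.t_end + pd.Timedelta(hours=window_h))
        for phase, mask in (("pre", pre_mask), ("post", post_mask)):
            steps = issf.build_steps(fx.loc[mask])
            if len(steps):
                phase_steps.append((eid, enc, phase, steps))
    if not phase_steps:
        raise ValueError("no usable steps in any encounter window")

    gammas = {"pre": pre_gamma, "post": post_gamma}
    if estimate_gamma:
        for phase in ("pre", "post"):
            lengths = np.concatenate(
                [s["length"].to_numpy() for e, enc_, ph, s in phase_steps if ph == phase]
            ) if any(ph == phase for _, _, ph, _ in phase_steps) else np.array([])
            if len(lengths) >= 30:
                gammas[phase] = issf.fit_gamma_lengths(lengths)

    designs = []
    stratum_offset = 0
    for eid, enc, phase, steps in phase_steps:
        gshape, gscale = gammas[phase]
        design = issf.build_design(
            steps, gshape, gscale, n_available,
            seed=int(rng.integers(2**31)), landscape=landscape,
        )
        design["stratum"] = design["stratum"] + stratum_offset
        stratum_offset = design["stratum"].max() + 1
        design["encounter_id"] = eid
        design["lion_id"] = enc.lion_id
        design["phase"] = phase
        boundary = enc.t_start if phase == "pre" else enc.t_end
        design["time_to_enc"] = (
            (pd.DatetimeIndex(design["t1"]) - boundary).total_seconds() / 3600.0
        )
        designs.append(design)
    design = pd.concat(designs, ignore_index=True)

    # endpoint covariates; cover proportions come from a disc-kernel
    # convolution of the class indicators (disc centred on the endpoint's
    # cell, sub-cell-identical to the per-point buffer computation)
    row, col = landscape.to_rowcol(design["x1"].to_numpy(), design["y1"].to_numpy())
    design["tri"] = tri_grid[row, col]
    shrub_grid, tree_grid = _cover_proportion_grids(landscape, buffer_diameter_m)
    design["shrub"] = shrub_grid[row, col]
    design["tree"] = tree_grid[row, col]

    dist_lion = np.full(len(design), np.nan)
    t1_h = pd.DatetimeIndex(design["t1"]).asi8 / 3.6e12
    for lid, lf in lion_by_id.items():
        sel = (design["lion_id"] == lid).to_numpy()
        if not sel.any():
            continue
        lt = pd.DatetimeIndex(lf["t"]).asi8 / 3.6e12
        idx = np.searchsorted(lt, t1_h[sel], side="right") - 1
        idx = np.clip(idx, 0, len(lf) - 1)
        dist_lion[sel] = np.hypot(
            design.loc[sel, "x1"].to_numpy() - lf["x"].to_numpy()[idx],
            design.loc[sel, "y1"].to_numpy() - lf["y"].to_numpy()[idx],
        )
    design["dist_lion"] = dist_lion

    std_cols = [c for c in ENCOUNTER_MAIN_EFFECTS + ["time_to_enc"]
                if design[c].std() > 0]
    design_std, scaling = standardize(design, std_cols)
    model_cols = list(issf.MOVEMENT_TERMS)
    for name in ENCOUNTER_MAIN_EFFECTS:
        model_cols.append(name)
        inter = f"{name}:time_to_enc"
        design_std[inter] = design_std[name] * design_std["time_to_enc"]
        model_cols.append(inter)
    design_std, _ = standardize(design_std, issf.MOVEMENT_TERMS)

    fit = issf.fit_clogit(design_std, model_cols)
    return design_std, fit
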