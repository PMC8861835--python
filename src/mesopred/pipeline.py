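"""End-to-end orchestration of the three analyses on a scenario.

``run_issf_comparison`` fits the five-candidate risk/reward model set
and ranks it by QIC; ``run_encounter_analysis`` detects encounters and
fits the movement-rate GAMM and the encounter-window iSSF;
``run_killsite_analysis`` builds ring-use records and fits the pre/post
probability-of-use models.  ``run_all`` chains them on one synthetic
scenario and writes CSV outputs plus a JSON run manifest.  A thin
argparse CLI exposes the same entry points.
"""

from __future__ import annotations

import argparse
import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import encounters as enc
from . import issf, killsites
from .covariates import standardize
from .simulate import Scenario, make_scenario

logger = logging.getLogger(__name__)

STANDARDIZED_COLUMNS = (
    issf.MOVEMENT_TERMS
    + issf.BASE_HABITAT
    + ["indirect_lion", "indirect_kill", "ln_direct_lion", "ln_direct_kill"]
)


def build_issf_table(scenario: Scenario, seed: int = 0) -> pd.DataFrame:
    """Observed/available design with all risk-reward covariates attached.

    Strata come from contiguous hourly fix triples of every coyote;
    habitat covariates, the indirect occurrence surfaces and the ln
    direct metrics are evaluated at step endpoints, and all predictors
    are centred and scaled over the pooled table.
    """
    rng = np.random.default_rng(seed)
    all_steps = []
    for track in scenario.coyote_tracks:
        steps = issf.build_steps(track)
        if len(steps):
            all_steps.append(steps)
    if not all_steps:
        raise ValueError("no usable strata in any coyote track")
    # availability gamma parameterized from the pooled observed step lengths
    gshape, gscale = issf.fit_gamma_lengths(
        pd.concat(all_steps)["length"].to_numpy()
    )
    designs = []
    offset = 0
    for steps in all_steps:
        d = issf.build_design(
            steps, gshape, gscale, seed=int(rng.integers(2**31)),
            landscape=scenario.landscape,
        )
        d["stratum"] = d["stratum"] + offset
        offset = d["stratum"].max() + 1
        designs.append(d)
    design = pd.concat(designs, ignore_index=True)
    design = issf.attach_habitat_covariates(design, scenario.landscape)
    design = issf.attach_indirect_surfaces(
        design,
        scenario.landscape.layers["lion_surface"],
        scenario.landscape.layers["kill_surface"],
        scenario.landscape,
    )
    design = issf.attach_direct_metrics(design, scenario.lion_fixes, scenario.kills)
    std_cols = [c for c in STANDARDIZED_COLUMNS if design[c].std() > 0]
    design, _ = standardize(design, std_cols)
    return design


def run_issf_comparison(
    scenario: Scenario, seed: int = 0, out_dir: str | Path | None = None
) -> dict:
    """Fit and rank the five candidate models; report the best model's
    coefficient summary."""
    design = build_issf_table(scenario, seed=seed)
    specs = issf.build_model_set(design.columns)
    fits = {name: issf.fit_clogit(design, cols) for name, cols in specs.items()}
    ranking = issf.rank_models(fits)
    best_name = ranking.loc[0, "model"]
    best = fits[best_name]
    result = {
        "ranking": ranking,
        "fits": fits,
        "best_model": best_name,
        "best_summary": best.summary(),
        "n_strata": best.n_strata,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ranking.to_csv(out_dir / "issf_ranking.csv", index=False)
        best.summary().to_csv(out_dir / "issf_best_model.csv")
    return result


def run_encounter_analysis(
    scenario: Scenario,
    seed: int = 0,
    out_dir: str | Path | None = None,
    rate_window_h: float = 5.0,
) -> dict:
    """Detect encounters, fit the movement-rate GAMM and encounter iSSF."""
    coyote_fixes = scenario.coyote_fixes
    lion_fixes = scenario.lion_fixes
    pairs = enc.detect_encounters(coyote_fixes, lion_fixes)
    bouts = enc.merge_bouts(pairs)
    independent = enc.filter_independent(bouts)
    result: dict = {
        "n_raw_pairs": len(pairs),
        "n_bouts": len(bouts),
        "n_independent": len(independent),
        "encounter_table": enc.encounters_to_frame(bouts),
    }
    if not independent:
        logger.warning("zero encounters detected; encounter outputs are empty")
        result.update(rate_fit=None, rate_curve=None, issf_fit=None,
                      multi_hour_fraction=float("nan"))
        return result
    result["multi_hour_fraction"] = float(
        np.mean([e.multi_hour for e in independent])
    )
    rate_records = enc.build_rate_records(
        coyote_fixes, independent, window_h=rate_window_h
    )
    result["rate_records"] = rate_records
    rate_fit = enc.fit_rate_model(rate_records)
    result["rate_fit"] = rate_fit
    grid = pd.DataFrame(
        {"time_to_encounter": np.r_[np.arange(-5.0, 0.0, 0.25),
                                    np.arange(0.25, 5.25, 0.25)]}
    )
    grid["hour_of_day"] = 12.0
    grid["coyote_id"] = "__population__"
    grid["encounter_id"] = -1
    rate_curve = pd.concat(
        [grid[["time_to_encounter"]], rate_fit.predict_with_ci(grid)], axis=1
    )
    result["rate_curve"] = rate_curve
    try:
        issf_design, issf_fit = enc.build_encounter_issf(
            coyote_fixes, lion_fixes, independent, scenario.landscape, seed=seed
        )
        result["issf_fit"] = issf_fit
        result["issf_summary"] = issf_fit.summary()
    except (ValueError, issf.ConvergenceError) as err:
        logger.warning("encounter iSSF not fitted: %s", err)
        result["issf_fit"] = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result["encounter_table"].to_csv(out_dir / "encounters.csv", index=False)
        rate_records.to_csv(out_dir / "rate_records.csv", index=False)
        rate_curve.to_csv(out_dir / "rate_curve.csv", index=False)
        if result.get("issf_fit") is not None:
            result["issf_summary"].to_csv(out_dir / "encounter_issf.csv")
    return result


def run_killsite_analysis(
    scenario: Scenario, out_dir: str | Path | None = None, fix_rate: float | None = None
) -> dict:
    """Ring-use records and pre/post probability-of-use models."""
    coyote_fixes = scenario.coyote_fixes
    if fix_rate is None:
        fix_rate = scenario.truth.extras.get("fix_success", 1.0)
    records = killsites.build_ring_records(scenario.kills, coyote_fixes, fix_rate)
    result: dict = {"records": records}
    for which in ("pre", "post"):
        n_kills = records.loc[records["which"] == which, "kill_id"].nunique()
        result[f"n_eligible_{which}"] = int(n_kills)
        try:
            fit, elim = killsites.fit_killsite_model(records, which)
            day_curve, ring_curve = killsites.predict_use_curves(fit, records, which)
            result[f"{which}_fit"] = fit
            result[f"{which}_elimination"] = elim
            result[f"{which}_day_curve"] = day_curve
            result[f"{which}_ring_curve"] = ring_curve
        except ValueError as err:
            logger.warning("%s-kill model not fitted: %s", which, err)
            result[f"{which}_fit"] = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        records.to_csv(out_dir / "ring_records.csv", index=False)
        for which in ("pre", "post"):
            if result.get(f"{which}_fit") is not None:
                result[f"{which}_fit"].term_summary().to_csv(
                    out_dir / f"killsite_{which}_terms.csv", index=False
                )
                result[f"{which}_day_curve"].to_csv(
                    out_dir / f"killsite_{which}_day_curve.csv", index=False
                )
                result[f"{which}_ring_curve"].to_csv(
                    out_dir / f"killsite_{which}_ring_curve.csv", index=False
                )
    return result


def run_all(seed: int, out_dir: str | Path | None = None, **scenario_kwargs) -> dict:
    """Simulate the default scenario and run all three analyses."""
    t0 = time.time()
    scenario = make_scenario(seed, **scenario_kwargs)
    stages = {}
    results = {"scenario": scenario}
    for name, fn in (
        ("issf", lambda: run_issf_comparison(
            scenario, seed=seed + 1,
            out_dir=out_dir and Path(out_dir) / "issf")),
        ("encounters", lambda: run_encounter_analysis(
            scenario, seed=seed + 2,
            out_dir=out_dir and Path(out_dir) / "encounters")),
        ("killsites", lambda: run_killsite_analysis(
            scenario, out_dir=out_dir and Path(out_dir) / "killsites")),
    ):
        t1 = time.time()
        results[name] = fn()
        stages[name] = round(time.time() - t1, 2)
    manifest = {
        "seed": seed,
        "selection_betas": scenario.truth.selection_betas,
        "n_coyotes": len(scenario.coyote_tracks),
        "n_lions": len(scenario.lion_tracks),
        "n_kills": int(len(scenario.kills)),
        "n_strata": results["issf"]["n_strata"],
        "n_raw_pairs": results["encounters"]["n_raw_pairs"],
        "n_bouts": results["encounters"]["n_bouts"],
        "n_independent_encounters": results["encounters"]["n_independent"],
        "n_eligible_pre": results["killsites"].get("n_eligible_pre"),
        "n_eligible_post": results["killsites"].get("n_eligible_post"),
        "stage_seconds": stages,
        "total_seconds": round(time.time() - t0, 2),
    }
    results["manifest"] = manifest
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def main(argv: list[str] | None = None) -> int:
    parser = argparse.ArgumentParser(
        prog="mesopred",
        description="Risk-reward movement analyses on synthetic GPS scenarios",
    )
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("mesopred_out"))
    parser.add_argument("--n-coyotes", type=int, default=4)
    parser.add_argument("--steps-per-coyote", type=int, default=1500)
    sub = parser.add_subparsers(dest="command", required=True)
    sub.add_parser("simulate", help="write the synthetic scenario (fixes, kills, rasters)")
    sub.add_parser("issf", help="five-model QIC comparison")
    p_enc = sub.add_parser("encounters", help="encounter detection and behaviour models")
    p_enc.add_argument("--dist-km", type=float, default=enc.DIST_KM_DEFAULT)
    p_enc.add_argument("--dt-h", type=float, default=enc.DT_H_DEFAULT)
    p_enc.add_argument("--gap-h", type=float, default=enc.GAP_H_DEFAULT)
    p_enc.add_argument("--window-h", type=float, default=5.0)
    sub.add_parser("killsites", help="ring-use records and pre/post models")
    sub.add_parser("all", help="run every analysis")
    args = parser.parse_args(argv)

    logging.basicConfig(level=logging.INFO, stream=sys.stderr,
                        format="%(levelname)s %(name)s: %(message)s")
    scenario = make_scenario(
        args.seed, n_coyotes=args.n_coyotes, steps_per_coyote=args.steps_per_coyote
    )
    args.out.mkdir(parents=True, exist_ok=True)
    if args.command == "simulate":
        from .simulate import fixes_to_csv, kills_to_csv

        fixes_to_csv(scenario.coyote_fixes, args.out / "coyote_fixes.csv")
        fixes_to_csv(scenario.lion_fixes, args.out / "lion_fixes.csv")
        kills_to_csv(scenario.kills, args.out / "kills.csv")
        scenario.landscape.write_ascii(args.out / "rasters")
    elif args.command == "issf":
        res = run_issf_comparison(scenario, seed=args.seed + 1, out_dir=args.out)
        print(res["ranking"].to_string(index=False))
    elif args.command == "encounters":
        pairs = enc.detect_encounters(
            scenario.coyote_fixes, scenario.lion_fixes, args.dist_km, args.dt_h
        )
        bouts = enc.filter_independent(enc.merge_bouts(pairs), args.gap_h)
        res = run_encounter_analysis(
            scenario, seed=args.seed + 2, out_dir=args.out,
            rate_window_h=args.window_h,
        )
        print(f"raw pairs={res['n_raw_pairs']} bouts={res['n_bouts']} "
              f"independent={len(bouts)} "
              f"multi_hour_fraction={res['multi_hour_fraction']:.3f}")
    elif args.command == "killsites":
        res = run_killsite_analysis(scenario, out_dir=args.out)
        print(f"eligible pre={res['n_eligible_pre']} post={res['n_eligible_post']}")
    elif args.command == "all":
        res = run_all(args.seed, out_dir=args.out,
                      n_coyotes=args.n_coyotes,
                      steps_per_coyote=args.steps_per_coyote)
        print(json.dumps(res["manifest"], indent=2))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
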