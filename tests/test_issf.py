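import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mesopred import issf
from mesopred.simulate import Track

from conftest import hourly, make_fixes


def _track_from_points(points, times=None):
    n = len(points)
    times = times if times is not None else hourly("2019-06-01", n)
    return Track(make_fixes("c1", "coyote", times, points))


class TestBuildSteps:
    def test_five_contiguous_fixes_give_three_strata(self):
        pts = [(0, 0), (100, 0), (200, 100), (250, 150), (300, 300)]
        steps = issf.build_steps(_track_from_points(pts))
        assert len(steps) == 3

    def test_gap_splits_bursts_and_no_step_spans_it(self):
        times = list(hourly("2019-06-01", 4)) + list(
            hourly("2019-06-01 06:00", 4)
        )
        pts = [(100 * i, 0) for i in range(8)]
        steps = issf.build_steps(_track_from_points(pts, times))
        # 4 fixes per burst -> 2 strata each; the 2-h+ gap contributes none
        assert len(steps) == 4
        gaps = (
            pd.DatetimeIndex(steps["t1"]) - pd.DatetimeIndex(steps["t0"])
        ).total_seconds() / 3600.0
        assert np.allclose(gaps, 1.0)

    def test_step_length_is_euclidean(self):
        # second step spans a 300-400-500 triangle; only it has a turn angle
        pts = [(0, 0), (10, 0), (310, 400)]
        steps = issf.build_steps(_track_from_points(pts))
        assert len(steps) == 1
        assert steps["length"].iloc[0] == pytest.approx(500.0)

    def test_short_track_warns_empty(self, caplog):
        steps = issf.build_steps(_track_from_points([(0, 0), (1, 1)]))
        assert len(steps) == 0


class TestSampleAvailable:
    def test_gamma_mean_at_study_parameters(self):
        rng = np.random.default_rng(0)
        lengths, _ = issf.sample_available(rng, 0.0, 0.38, 1402.57, n=10_000)
        assert lengths.mean() == pytest.approx(0.38 * 1402.57, rel=0.05)

    def test_angles_uniform_ks(self):
        rng = np.random.default_rng(1)
        _, angles = issf.sample_available(rng, 0.0, 0.38, 1402.57, n=10_000)
        p = stats.kstest(angles, stats.uniform(loc=-np.pi, scale=2 * np.pi).cdf).pvalue
        assert p > 0.01

    def test_default_candidate_count(self):
        rng = np.random.default_rng(2)
        lengths, angles = issf.sample_available(rng, 0.0, 1.0, 1.0)
        assert len(lengths) == len(angles) == 10

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            issf.sample_available(np.random.default_rng(0), 0.0, -1.0, 1.0)


def _toy_design(n_strata=80, beta_true=0.8, seed=0, n_avail=10):
    """Conditional-logistic data with one binary covariate, known truth."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_strata):
        x = rng.integers(0, 2, n_avail + 1).astype(float)
        w = np.exp(beta_true * x)
        obs = rng.choice(n_avail + 1, p=w / w.sum())
        for j in range(n_avail + 1):
            rows.append(
                {"stratum": s, "case": int(j == obs), "coyote_id": f"c{s % 4}",
                 "x": x[j]}
            )
    return pd.DataFrame(rows)


def grid_search_ll(design, cols, betas):
    """Independent likelihood evaluation for the grid-search oracle."""
    X = design[cols].to_numpy()
    ll = 0.0
    for _, grp in design.groupby("stratum"):
        eta = grp[cols].to_numpy() @ betas
        ll += eta[grp["case"].to_numpy() == 1][0] - np.log(np.exp(eta).sum())
    return ll


class TestFitClogit:
    def test_null_likelihood_is_log_one_eleventh_per_stratum(self):
        # with 1 observed + 10 available and beta = 0 every step is
        # equally likely, so the quasi-likelihood is n * ln(1/11) exactly
        d = _toy_design(n_strata=30, beta_true=0.0, seed=1)
        ll0 = issf._clogit_ll(
            d[["x"]].to_numpy(), np.zeros(1),
            pd.factorize(d["stratum"])[0],
            d["case"].to_numpy().astype(bool),
            d["stratum"].nunique(),
        )
        assert ll0 == pytest.approx(30 * np.log(1 / 11), abs=1e-12)

    def test_matches_grid_search_oracle(self):
        d = _toy_design(n_strata=120, beta_true=0.8, seed=2)
        fit = issf.fit_clogit(d, ["x"])
        grid = np.arange(-0.5, 2.5, 1e-3)
        lls = [grid_search_ll(d, ["x"], np.array([b])) for b in grid]
        best = grid[int(np.argmax(lls))]
        assert fit.params["x"] == pytest.approx(best, abs=1e-3)
        assert fit.quasi_ll == pytest.approx(max(lls), abs=1e-6)

    def test_matches_statsmodels_conditional_logit(self):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        rng = np.random.default_rng(3)
        d = _toy_design(n_strata=100, beta_true=0.6, seed=3)
        d["z"] = rng.normal(size=len(d))
        fit = issf.fit_clogit(d, ["x", "z"])
        sm_fit = ConditionalLogit(
            d["case"], d[["x", "z"]], groups=d["stratum"]
        ).fit(disp=0)
        # agreement to the two solvers' convergence tolerances
        np.testing.assert_allclose(fit.params, sm_fit.params, atol=2e-4)
        np.testing.assert_allclose(
            np.sqrt(np.diag(fit.naive_cov)), sm_fit.bse, atol=2e-4
        )

    def test_invariant_to_within_stratum_order(self):
        d = _toy_design(n_strata=50, seed=4)
        shuffled = d.sample(frac=1.0, random_state=0)
        f1 = issf.fit_clogit(d, ["x"])
        f2 = issf.fit_clogit(shuffled, ["x"])
        assert f1.params["x"] == pytest.approx(f2.params["x"], abs=1e-10)

    def test_stratum_constant_shift_changes_nothing(self):
        d = _toy_design(n_strata=50, seed=5)
        f1 = issf.fit_clogit(d, ["x"])
        shifted = d.copy()
        shifted["x"] = shifted["x"] + shifted["stratum"] * 3.0
        f2 = issf.fit_clogit(shifted, ["x"])
        assert f2.params["x"] == pytest.approx(f1.params["x"], abs=1e-8)
        assert f2.quasi_ll == pytest.approx(f1.quasi_ll, abs=1e-8)

    def test_affine_rescaling_rescales_beta(self):
        d = _toy_design(n_strata=50, seed=6)
        f1 = issf.fit_clogit(d, ["x"])
        scaled = d.copy()
        scaled["x"] = scaled["x"] * 2.0
        f2 = issf.fit_clogit(scaled, ["x"])
        assert f2.params["x"] == pytest.approx(f1.params["x"] / 2.0, abs=1e-8)

    def test_separation_raises_naming_covariate(self):
        d = _toy_design(n_strata=40, seed=7)
        d["sep"] = d["case"].astype(float)  # perfectly predicts the case
        with pytest.raises(issf.ConvergenceError, match="sep"):
            issf.fit_clogit(d, ["x", "sep"])

    def test_malformed_strata_rejected(self):
        d = _toy_design(n_strata=10, seed=8)
        case_row = d.index[(d["stratum"] == 0) & (d["case"] == 1)][0]
        d.loc[case_row, "case"] = 0  # stratum 0 now has no observed step
        with pytest.raises(ValueError):
            issf.fit_clogit(d, ["x"])


class TestQic:
    def test_identity_when_robust_equals_naive(self):
        d = _toy_design(n_strata=60, seed=9)
        fit = issf.fit_clogit(d, ["x"])
        forced = issf.ClogitFit(
            params=fit.params,
            naive_cov=fit.naive_cov,
            robust_cov=fit.naive_cov,
            quasi_ll=fit.quasi_ll,
            n_strata=fit.n_strata,
            n_clusters=fit.n_clusters,
            n_iter=fit.n_iter,
            columns=fit.columns,
        )
        assert issf.qic(forced) == pytest.approx(
            -2 * fit.quasi_ll + 2 * fit.K, abs=1e-9
        )

    def test_doubling_clusters_matches_hand_formula(self):
        d = _toy_design(n_strata=40, seed=10)
        doubled = pd.concat(
            [d, d.assign(stratum=d["stratum"] + 1000,
                         coyote_id=d["coyote_id"] + "_dup")],
            ignore_index=True,
        )
        f1 = issf.fit_clogit(d, ["x"])
        f2 = issf.fit_clogit(doubled, ["x"])
        assert f2.params["x"] == pytest.approx(f1.params["x"], abs=1e-8)
        A = np.linalg.inv(f2.naive_cov.to_numpy())
        expect = -2 * f2.quasi_ll + 2 * np.trace(A @ f2.robust_cov.to_numpy())
        assert issf.qic(f2) == pytest.approx(expect, abs=1e-9)


class TestModelSet:
    COLUMNS = (
        issf.MOVEMENT_TERMS + issf.BASE_HABITAT
        + ["indirect_lion", "indirect_kill", "ln_direct_lion", "ln_direct_kill"]
    )

    def test_base_has_twelve_augmented_fourteen(self):
        specs = issf.build_model_set(self.COLUMNS)
        assert len(specs) == 5
        assert len(specs["base"]) == 12
        for name, cols in specs.items():
            if name != "base":
                assert len(cols) == 14
            assert len(set(cols)) == len(cols)

    def test_missing_covariate_named(self):
        with pytest.raises(ValueError, match="indirect_lion"):
            issf.build_model_set(issf.MOVEMENT_TERMS + issf.BASE_HABITAT)


class TestRankModels:
    def test_identical_fits_tie_at_zero(self):
        d = _toy_design(n_strata=40, seed=11)
        fit = issf.fit_clogit(d, ["x"])
        table = issf.rank_models({"m1": fit, "m2": fit})
        assert np.allclose(table["delta_qic"], 0.0)

    def test_best_model_delta_zero_and_sorted(self):
        d = _toy_design(n_strata=80, beta_true=1.0, seed=12)
        d["noise"] = np.random.default_rng(0).normal(size=len(d))
        f_good = issf.fit_clogit(d, ["x"])
        f_noise = issf.fit_clogit(d, ["noise"])
        table = issf.rank_models({"signal": f_good, "noise": f_noise})
        assert table.loc[0, "model"] == "signal"
        assert table.loc[0, "delta_qic"] == 0.0
        assert table["delta_qic"].is_monotonic_increasing

    def test_different_strata_sets_rejected(self):
        f1 = issf.fit_clogit(_toy_design(n_strata=30, seed=13), ["x"])
        f2 = issf.fit_clogit(_toy_design(n_strata=40, seed=13), ["x"])
        with pytest.raises(ValueError):
            issf.rank_models({"a": f1, "b": f2})
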