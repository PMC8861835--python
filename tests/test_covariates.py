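import numpy as np
import pandas as pd
import pytest

from mesopred import covariates as cov
from mesopred.grids import COVER_OPEN, COVER_SHRUB, Landscape


def brute_tri(elev):
    ny, nx = elev.shape
    out = np.zeros_like(elev, dtype=float)
    for r in range(ny):
        for c in range(nx):
            s = 0.0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < ny and 0 <= cc < nx:
                        s += (elev[r, c] - elev[rr, cc]) ** 2
            out[r, c] = np.sqrt(s)
    return out


def brute_tpi(elev, w):
    ny, nx = elev.shape
    h = w // 2
    out = np.zeros_like(elev, dtype=float)
    for r in range(ny):
        for c in range(nx):
            vals = [
                elev[rr, cc]
                for rr in range(max(r - h, 0), min(r + h + 1, ny))
                for cc in range(max(c - h, 0), min(c + h + 1, nx))
                if (rr, cc) != (r, c)
            ]
            out[r, c] = elev[r, c] - np.mean(vals)
    return out


class TestTerrainIndices:
    def test_flat_grid_zero(self):
        flat = np.full((8, 8), 1234.0)
        assert np.all(cov.compute_tri(flat) == 0)
        assert np.allclose(cov.compute_tpi(flat), 0)

    def test_single_peak_hand_values(self):
        elev = np.zeros((3, 3))
        elev[1, 1] = 10.0
        assert cov.compute_tri(elev)[1, 1] == pytest.approx(np.sqrt(800), abs=1e-9)
        assert cov.compute_tpi(elev)[1, 1] == pytest.approx(10.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_random_grids(self, seed):
        elev = np.random.default_rng(seed).uniform(1000, 3000, (16, 16))
        np.testing.assert_allclose(cov.compute_tri(elev), brute_tri(elev), atol=1e-9)
        np.testing.assert_allclose(cov.compute_tpi(elev), brute_tpi(elev, 3), atol=1e-9)

    def test_tri_nonnegative(self):
        elev = np.random.default_rng(3).uniform(0, 100, (12, 12))
        assert cov.compute_tri(elev).min() >= 0

    def test_constant_gradient_plane_tpi_zero_interior(self):
        elev = np.outer(np.arange(10), np.ones(10)) * 5.0
        tpi = cov.compute_tpi(elev)
        np.testing.assert_allclose(tpi[1:-1, 1:-1], 0.0, atol=1e-9)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            cov.compute_tpi(np.zeros((5, 5)), window_cells=4)
        with pytest.raises(ValueError):
            cov.compute_tri(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            cov.compute_tri(np.full((5, 5), np.nan))


def _cover_landscape(cover):
    return Landscape(origin=(0.0, 0.0), resolution=30.0, layers={"cover": cover})


class TestCoverProportions:
    def test_uniform_grid(self):
        L = _cover_landscape(np.full((20, 20), float(COVER_SHRUB)))
        p = cov.cover_proportions(L, 300.0, 300.0)
        assert p["shrub"] == pytest.approx(1.0)

    def test_proportions_sum_to_one_everywhere(self):
        rng = np.random.default_rng(1)
        L = _cover_landscape(rng.integers(0, 3, (20, 20)).astype(float))
        for _ in range(25):
            x, y = rng.uniform(30, 560, 2)
            p = cov.cover_proportions(L, x, y)
            assert abs(sum(p.values()) - 1.0) < 1e-9

    def test_half_plane_split(self):
        cover = np.full((40, 40), float(COVER_OPEN))
        cover[:, 20:] = COVER_SHRUB
        L = _cover_landscape(cover)
        p = cov.cover_proportions(L, 20 * 30.0, 600.0, buffer_diameter_m=256.0)
        # within one cell-row of discretization of an even split
        assert p["open"] == pytest.approx(0.5, abs=0.1)
        assert p["shrub"] == pytest.approx(0.5, abs=0.1)

    def test_tiny_buffer_degenerates_to_cell_class(self):
        cover = np.full((20, 20), float(COVER_OPEN))
        L = _cover_landscape(cover)
        p = cov.cover_proportions(L, 300.0, 300.0, buffer_diameter_m=1.0)
        assert p["open"] == 1.0


class TestStandardize:
    def test_hand_example_n_minus_one(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        out, rec = cov.standardize(df, ["a"])
        np.testing.assert_allclose(out["a"], [-1.0, 0.0, 1.0])
        assert rec.sds["a"] == pytest.approx(1.0)

    def test_idempotent_and_invertible(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"a": rng.normal(5, 3, 100)})
        once, rec = cov.standardize(df, ["a"])
        twice, _ = cov.standardize(once, ["a"])
        np.testing.assert_allclose(once["a"], twice["a"], atol=1e-12)
        back = rec.invert(once)
        np.testing.assert_allclose(back["a"], df["a"], atol=1e-12)

    def test_zero_variance_named_in_error(self):
        df = pd.DataFrame({"flat": np.ones(10)})
        with pytest.raises(ValueError, match="flat"):
            cov.standardize(df, ["flat"])


class TestVifPrune:
    def test_orthogonal_columns_untouched(self):
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.normal(size=(50, 3)))
        df = pd.DataFrame(q, columns=list("abc"))
        kept, log = cov.vif_prune(df)
        assert kept == list("abc")
        assert len(log) == 0

    def test_duplicate_column_removed_once(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=60)
        df = pd.DataFrame({"a": a, "dup": a, "b": rng.normal(size=60)})
        kept, log = cov.vif_prune(df)
        assert sorted(kept) == ["b", "dup"] or sorted(kept) == ["a", "b"]
        assert len(log) == 1 and np.isinf(log["vif"].iloc[0])

    def test_known_bivariate_vif(self):
        # r = 0.9 between two columns -> VIF = 1/(1-0.81) ~ 5.26
        rng = np.random.default_rng(3)
        n = 20000
        x = rng.normal(size=n)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": y, "z": rng.normal(size=n)})
        kept, log = cov.vif_prune(df, threshold=3.0)
        assert len(log) == 1
        assert log["vif"].iloc[0] == pytest.approx(1 / (1 - 0.81), rel=0.1)
        assert "z" in kept and len(kept) == 2

    def test_terminates_within_column_budget(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(80, 2))
        df = pd.DataFrame(
            {
                "a": base[:, 0],
                "b": base[:, 0] + 0.01 * rng.normal(size=80),
                "c": base[:, 1],
                "d": base[:, 1] + 0.01 * rng.normal(size=80),
            }
        )
        kept, log = cov.vif_prune(df)
        assert len(log) <= len(df.columns) - 1
        assert len(kept) >= 2


class TestRocCutoff:
    def test_enumerated_example(self):
        thr = cov.roc_cutoff([0.9, 0.8, 0.4, 0.2], [1, 1, 0, 0])
        assert 0.4 < thr <= 0.8
        scores = np.array([0.9, 0.8, 0.4, 0.2])
        labels = np.array([1, 1, 0, 0], dtype=bool)
        pred = scores >= thr
        assert (pred & labels).sum() / labels.sum() == 1.0
        assert (pred & ~labels).sum() == 0

    def test_perfectly_separable_full_sensitivity(self):
        rng = np.random.default_rng(0)
        scores = np.r_[rng.uniform(0.6, 1.0, 50), rng.uniform(0.0, 0.4, 50)]
        labels = np.r_[np.ones(50), np.zeros(50)].astype(bool)
        thr = cov.roc_cutoff(scores, labels)
        pred = scores >= thr
        assert (pred & labels).sum() / labels.sum() == 1.0
        assert (pred & ~labels).sum() / (~labels).sum() <= 0.05

    def test_infeasible_constraint_warns(self):
        with pytest.warns(UserWarning):
            thr = cov.roc_cutoff([0.5, 0.5], [1, 0], max_fpr=0.0)
        assert thr > 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cov.roc_cutoff([0.1, 0.2], [1, 1])


class TestOccurrenceSurface:
    def test_elevation_driven_points_recovered(self, landscape):
        rng = np.random.default_rng(11)
        elev = landscape.layers["elevation"]
        ny, nx = landscape.shape
        rr, cc = np.mgrid[0:ny, 0:nx]
        p = np.exp(2.5 * (elev - elev.mean()) / elev.std())
        idx = rng.choice(ny * nx, size=300, p=(p / p.sum()).ravel())
        ux, uy = landscape.cell_center(rr.ravel()[idx], cc.ravel()[idx])
        aidx = rng.choice(ny * nx, size=300)
        ax, ay = landscape.cell_center(rr.ravel()[aidx], cc.ravel()[aidx])
        surf = cov.fit_occurrence_surface(
            np.c_[ux, uy], np.c_[ax, ay], landscape, seed=0
        )
        from scipy.stats import spearmanr

        rho = spearmanr(surf.grid.ravel(), elev.ravel()).statistic
        assert rho > 0.5
        assert surf.grid.min() >= 0 and surf.grid.max() <= 1
        assert surf.provenance == "internal classifier"

    def test_uninformative_points_give_flatter_surface(self, landscape):
        rng = np.random.default_rng(12)
        ny, nx = landscape.shape
        rr, cc = np.mgrid[0:ny, 0:nx]
        elev = landscape.layers["elevation"]
        p = np.exp(2.5 * (elev - elev.mean()) / elev.std())
        informative = rng.choice(ny * nx, size=300, p=(p / p.sum()).ravel())
        flat_u = rng.choice(ny * nx, size=300)
        avail = rng.choice(ny * nx, size=300)

        def surf_for(used_idx):
            ux, uy = landscape.cell_center(rr.ravel()[used_idx], cc.ravel()[used_idx])
            ax, ay = landscape.cell_center(rr.ravel()[avail], cc.ravel()[avail])
            return cov.fit_occurrence_surface(
                np.c_[ux, uy], np.c_[ax, ay], landscape, seed=1
            )

        assert surf_for(flat_u).grid.std() < surf_for(informative).grid.std()
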