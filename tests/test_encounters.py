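import numpy as np
import pandas as pd
import pytest

from mesopred import encounters as enc
from mesopred import simulate

from conftest import hourly, make_fixes

T = pd.Timestamp


def brute_pairs(coyote, lion, dist_km=1.0, dt_h=2.0):
    out = []
    for i in range(len(coyote)):
        for j in range(len(lion)):
            d = np.hypot(
                coyote["x"].iloc[i] - lion["x"].iloc[j],
                coyote["y"].iloc[i] - lion["y"].iloc[j],
            )
            dt = abs(
                (coyote["t"].iloc[i] - lion["t"].iloc[j]).total_seconds() / 3600.0
            )
            if d <= dist_km * 1000.0 and dt <= dt_h:
                out.append((i, j))
    return out


class TestDetectEncounters:
    def test_parallel_distant_tracks_no_pairs(self):
        times = hourly("2019-06-01", 10)
        coyote = make_fixes("c1", "coyote", times, [(i * 100.0, 0.0) for i in range(10)])
        lion = make_fixes("l1", "lion", times, [(i * 100.0, 5000.0) for i in range(10)])
        assert len(enc.detect_encounters(coyote, lion)) == 0

    def test_threshold_arithmetic_pair(self):
        coyote = make_fixes(
            "c1", "coyote", [T("2019-06-01 10:00", tz="UTC")], [(0.0, 0.0)]
        )
        lion = make_fixes(
            "l1", "lion", [T("2019-06-01 11:30", tz="UTC")], [(0.0, 900.0)]
        )
        pairs = enc.detect_encounters(coyote, lion)
        assert len(pairs) == 1
        assert pairs["dist_m"].iloc[0] == pytest.approx(900.0)

    def test_outside_time_window_excluded(self):
        coyote = make_fixes(
            "c1", "coyote", [T("2019-06-01 10:00", tz="UTC")], [(0.0, 0.0)]
        )
        lion = make_fixes(
            "l1", "lion", [T("2019-06-02 11:00", tz="UTC")], [(0.0, 900.0)]
        )
        assert len(enc.detect_encounters(coyote, lion)) == 0

    def test_boundary_values_inclusive(self):
        coyote = make_fixes(
            "c1", "coyote", [T("2019-06-01 10:00", tz="UTC")], [(0.0, 0.0)]
        )
        lion = make_fixes(
            "l1", "lion", [T("2019-06-01 12:00", tz="UTC")], [(1000.0, 0.0)]
        )
        assert len(enc.detect_encounters(coyote, lion)) == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_on_random_tracks(self, seed):
        rng = np.random.default_rng(seed)
        nc, nl = rng.integers(5, 40), rng.integers(5, 40)
        t0 = T("2019-06-01", tz="UTC")
        coyote = make_fixes(
            "c1", "coyote",
            t0 + pd.to_timedelta(np.sort(rng.uniform(0, 72, nc)), unit="h"),
            rng.uniform(0, 4000, (nc, 2)),
        )
        lion = make_fixes(
            "l1", "lion",
            t0 + pd.to_timedelta(np.sort(rng.uniform(0, 72, nl)), unit="h"),
            rng.uniform(0, 4000, (nl, 2)),
        )
        pairs = enc.detect_encounters(coyote, lion)
        assert len(pairs) == len(brute_pairs(coyote, lion))

    def test_empty_inputs(self):
        empty = make_fixes("c1", "coyote", [], np.zeros((0, 2)))
        other = make_fixes("l1", "lion", hourly("2019-06-01", 3), np.zeros((3, 2)))
        assert len(enc.detect_encounters(empty, other)) == 0


def _pairs_at(times_str, coyote_id="c1", lion_id="l1"):
    times = pd.DatetimeIndex([T(s, tz="UTC") for s in times_str])
    return pd.DataFrame(
        {
            "coyote_id": coyote_id,
            "lion_id": lion_id,
            "t_coyote": times,
            "t_lion": times,
            "x_coyote": 0.0, "y_coyote": 0.0,
            "x_lion": 0.0, "y_lion": 0.0,
            "dist_m": 500.0, "dt_h": 0.0,
        }
    )


class TestMergeBouts:
    def test_consecutive_fixes_merge(self):
        bouts = enc.merge_bouts(
            _pairs_at(["2019-06-01 10:00", "2019-06-01 11:00", "2019-06-01 12:00"])
        )
        assert len(bouts) == 1
        assert bouts[0].t_start == T("2019-06-01 10:00", tz="UTC")
        assert bouts[0].t_end == T("2019-06-01 12:00", tz="UTC")
        assert bouts[0].multi_hour

    def test_single_fix_single_point_bout(self):
        bouts = enc.merge_bouts(_pairs_at(["2019-06-01 10:00"]))
        assert len(bouts) == 1
        assert bouts[0].t_start == bouts[0].t_end
        assert not bouts[0].multi_hour

    def test_gap_splits_bouts(self):
        bouts = enc.merge_bouts(
            _pairs_at(["2019-06-01 10:00", "2019-06-01 14:00"])
        )
        assert len(bouts) == 2


class TestFilterIndependent:
    @staticmethod
    def _enc(start, end, coyote="c1"):
        return enc.Encounter(
            coyote, "l1", T(start, tz="UTC"), T(end, tz="UTC"), n_pairs=1
        )

    def test_close_successor_dropped(self):
        first = self._enc("2019-06-01 10:00", "2019-06-01 12:00")
        second = self._enc("2019-06-01 15:00", "2019-06-01 15:00")
        kept = enc.filter_independent([first, second])
        assert kept == [first]
        assert not second.independent

    def test_exactly_five_hours_retained(self):
        first = self._enc("2019-06-01 10:00", "2019-06-01 12:00")
        second = self._enc("2019-06-01 17:00", "2019-06-01 17:00")
        assert len(enc.filter_independent([first, second])) == 2

    def test_single_encounter_retained(self):
        only = self._enc("2019-06-01 10:00", "2019-06-01 10:00")
        assert enc.filter_independent([only]) == [only]

    def test_other_coyote_not_blocked(self):
        a = self._enc("2019-06-01 10:00", "2019-06-01 12:00", "c1")
        b = self._enc("2019-06-01 13:00", "2019-06-01 13:00", "c2")
        assert len(enc.filter_independent([a, b])) == 2

    def test_pipeline_idempotent(self):
        encs = [
            self._enc("2019-06-01 10:00", "2019-06-01 12:00"),
            self._enc("2019-06-01 14:00", "2019-06-01 14:00"),
            self._enc("2019-06-02 10:00", "2019-06-02 11:00"),
        ]
        once = enc.filter_independent(encs)
        twice = enc.filter_independent(list(once))
        assert once == twice


class TestExtractWindows:
    def _track(self):
        # constant 500 m/h eastward movement across 30 hours
        times = hourly("2019-06-01", 30)
        return make_fixes("c1", "coyote", times, [(500.0 * i, 0.0) for i in range(30)])

    def test_rates_and_sign_convention(self):
        fixes = self._track()
        e = enc.Encounter(
            "c1", "l1",
            T("2019-06-01 10:00", tz="UTC"), T("2019-06-01 12:00", tz="UTC"), 3,
        )
        rec = enc.extract_windows(fixes, e, 0, window_h=5.0)
        assert np.allclose(rec["rate"], 500.0)
        assert rec["time_to_encounter"].min() == -5.0
        assert rec["time_to_encounter"].max() == 5.0
        # fix at t_start - 3 h carries time_to_encounter = -3
        assert -3.0 in rec["time_to_encounter"].values

    def test_in_bout_fixes_excluded(self):
        fixes = self._track()
        e = enc.Encounter(
            "c1", "l1",
            T("2019-06-01 10:00", tz="UTC"), T("2019-06-01 12:00", tz="UTC"), 3,
        )
        rec = enc.extract_windows(fixes, e, 0, window_h=5.0)
        assert not ((rec["time_to_encounter"] >= 0) & (rec["time_to_encounter"] <= 0)).any()
        assert len(rec) == 10  # 5 pre + 5 post


class TestRateModel:
    def test_peak_at_encounter_recovered(self):
        rng = np.random.default_rng(0)
        rows = []
        for eid in range(40):
            for tte in list(range(-5, 0)) + list(range(1, 6)):
                mu = 400.0 + 700.0 * np.exp(-0.5 * tte**2)
                rows.append(
                    {
                        "coyote_id": f"c{eid % 6}",
                        "encounter_id": eid,
                        "time_to_encounter": float(tte),
                        "hour_of_day": float((eid + tte) % 24),
                        "rate": rng.gamma(6.0, mu / 6.0),
                    }
                )
        rec = pd.DataFrame(rows)
        fit = enc.fit_rate_model(rec)
        grid = pd.DataFrame({"time_to_encounter": np.linspace(-5, 5, 101)})
        grid["hour_of_day"] = 12.0
        grid["coyote_id"] = "zz"
        grid["encounter_id"] = -1
        pred = fit.predict(grid)
        argmax = grid["time_to_encounter"][int(np.argmax(pred))]
        assert abs(argmax) <= 1.0

    def test_constant_rates_shrink_smooth(self):
        rng = np.random.default_rng(1)
        rec = pd.DataFrame(
            {
                "coyote_id": "c1",
                "encounter_id": np.repeat(np.arange(30), 10),
                "time_to_encounter": np.tile(
                    list(range(-5, 0)) + list(range(1, 6)), 30
                ).astype(float),
                "hour_of_day": rng.uniform(0, 24, 300),
                "rate": rng.gamma(25.0, 500 / 25.0, 300),
            }
        )
        fit = enc.fit_rate_model(rec)
        # penalized to (near-)linear: far below the k=8 basis ceiling
        assert fit.edf_by_term["cs(time_to_encounter)"] < 2.0

    def test_nonpositive_rates_floored(self):
        rec = pd.DataFrame(
            {
                "coyote_id": "c1",
                "encounter_id": np.repeat(np.arange(20), 10),
                "time_to_encounter": np.tile(
                    list(range(-5, 0)) + list(range(1, 6)), 20
                ).astype(float),
                "hour_of_day": np.tile(np.arange(10), 20).astype(float),
                "rate": np.r_[0.0, np.random.default_rng(2).gamma(4, 100, 199)],
            }
        )
        fit = enc.fit_rate_model(rec)  # must not raise on the zero rate
        assert fit.family == "gamma"


class TestEncounterIssfPipeline:
    def test_counts_deterministic_and_pipeline_runs(self):
        sc = simulate.make_scenario(11, n_coyotes=2, steps_per_coyote=600,
                                    extent=(128, 128))
        pairs1 = enc.detect_encounters(sc.coyote_fixes, sc.lion_fixes)
        pairs2 = enc.detect_encounters(sc.coyote_fixes, sc.lion_fixes)
        assert len(pairs1) == len(pairs2)
        bouts = enc.merge_bouts(pairs1)
        indep = enc.filter_independent(bouts)
        assert len(indep) <= len(bouts)
        if len(indep) >= 3:
            design, fit = enc.build_encounter_issf(
                sc.coyote_fixes, sc.lion_fixes, indep, sc.landscape, seed=0
            )
            assert "dist_lion:time_to_enc" in fit.params.index
            # every stratum is 1 observed + 10 available
            sizes = design.groupby("stratum")["case"].agg(["size", "sum"])
            assert (sizes["size"] == 11).all()
            assert (sizes["sum"] == 1).all()
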