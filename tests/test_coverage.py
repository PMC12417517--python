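"""Distance summaries, benefit profiles, availability, and type tables."""

import numpy as np
import pandas as pd
import pytest

from aed_golden import (CityConfig, WalkWindow, benefit_profile,
                        filter_available, generate_city,
                        golden_window_coverage, square_region,
                        summarize_distances, type_cross_table, uniform_events)
from aed_golden.synth import lattice_points

from reference_data import (REFERENCE_PROFILE, REFERENCE_TYPE_COUNTS,
                            REFERENCE_TYPE_PCT)


def sort_based_quantile_oracle(values, q):
    """From-scratch linear-interpolation quantile (independent of numpy's)."""
    v = sorted(values)
    pos = q * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (pos - lo) * (v[hi] - v[lo])


class TestSummarizeDistances:
    def test_simple_vector(self):
        s = summarize_distances([0, 100, 200, 300, 400])
        assert (s.min, s.median, s.max, s.mean) == (0, 200, 400, 200)

    def test_single_value_population_mode(self):
        s = summarize_distances([50.0], sample_sd=False)
        assert s.min == s.q1 == s.median == s.q3 == s.max == 50.0
        assert s.sd == 0.0

    def test_matches_sort_based_oracle(self, rng):
        vals = rng.exponential(200.0, 1000)
        s = summarize_distances(vals)
        assert s.q1 == pytest.approx(sort_based_quantile_oracle(vals, 0.25))
        assert s.median == pytest.approx(sort_based_quantile_oracle(vals, 0.50))
        assert s.q3 == pytest.approx(sort_based_quantile_oracle(vals, 0.75))
        assert s.min <= s.q1 <= s.median <= s.q3 <= s.max

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            summarize_distances([])


class TestBenefitProfile:
    def test_colocated_pairs_saturate(self):
        pts = np.array([[10.0, 10.0], [500.0, 500.0], [900.0, 100.0]])
        prof = benefit_profile(pts, pts.copy(), radii=[100, 200, 300])
        assert np.allclose(prof.avg_devices, [1, 1, 1])
        assert np.allclose(prof.pct_covered, [100, 100, 100])

    def test_radii_must_increase(self):
        with pytest.raises(ValueError):
            benefit_profile([[0, 0]], [[0, 0]], radii=[200, 100])

    def test_route_metric_requires_graph(self):
        with pytest.raises(ValueError, match="graph"):
            benefit_profile([[0, 0]], [[0, 0]], radii=[100], metric="route")

    def test_poisson_closed_form(self):
        # homogeneous device placement: avg(r) = lambda pi r^2 and
        # pct(r) = 100 (1 - exp(-lambda pi r^2)); r=100 m at 10/km^2
        # gives 0.314 and 27.0%
        region = square_region(10_000.0)
        lam = 10 / 1e6  # per m^2
        r = 100.0
        expect_avg = lam * np.pi * r**2
        expect_pct = 100 * (1 - np.exp(-expect_avg))
        avgs, pcts = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            devices = uniform_events(region, 1000, rng)
            events = uniform_events(region, 2000, rng)
            prof = benefit_profile(events, devices, radii=[r])
            avgs.append(prof.avg_devices[0])
            pcts.append(prof.pct_covered[0])
        se_avg = np.std(avgs, ddof=1) / np.sqrt(5)
        se_pct = np.std(pcts, ddof=1) / np.sqrt(5)
        assert abs(np.mean(avgs) - expect_avg) < 3 * max(se_avg, 0.004)
        assert abs(np.mean(pcts) - expect_pct) < 3 * max(se_pct, 0.3)

    def test_lattice_closed_form(self, rng):
        # devices on a square lattice of spacing s, r = s/2: the disk covers
        # pi/4 of each unit cell, so pct = 78.5% and avg = 0.785
        s = 540.0
        region = square_region(10 * s)
        devices = lattice_points(region, s)
        events = uniform_events(region, 20_000, rng)
        prof = benefit_profile(events, devices, radii=[s / 2])
        assert prof.pct_covered[0] == pytest.approx(100 * np.pi / 4, rel=0.02)
        assert prof.avg_devices[0] == pytest.approx(np.pi / 4, rel=0.02)

    def test_profile_invariants_on_synthetic_city(self, small_city):
        prof = benefit_profile(small_city.event_xy, small_city.device_xy)
        assert np.all(np.diff(prof.avg_devices) >= 0)
        assert np.all(np.diff(prof.pct_covered) >= 0)
        assert np.all(prof.avg_devices >= prof.pct_covered / 100 - 1e-12)

    def test_adding_a_device_never_decreases_profile(self, rng):
        ev = rng.uniform(0, 2000, (100, 2))
        dv = rng.uniform(0, 2000, (30, 2))
        base = benefit_profile(ev, dv, radii=[150, 300])
        more = benefit_profile(ev, np.vstack([dv, [[1000, 1000]]]), radii=[150, 300])
        assert np.all(more.avg_devices >= base.avg_devices)
        assert np.all(more.pct_covered >= base.pct_covered)


class TestReferenceProfileFixture:
    def test_printed_profile_satisfies_model_invariants(self):
        radii = sorted(REFERENCE_PROFILE)
        avg = [REFERENCE_PROFILE[r][0] for r in radii]
        pct = [REFERENCE_PROFILE[r][1] for r in radii]
        assert all(np.diff(avg) >= 0)
        assert all(np.diff(pct) >= 0)
        for a, p in zip(avg, pct):
            assert a >= p / 100


class TestGoldenWindowCoverage:
    def test_budget_zero_counts_colocated_only(self, small_city):
        window = WalkWindow(duration=1e-9, speed=1.5)
        pct, avg, counts = golden_window_coverage(
            small_city.event_xy, small_city.device_xy, small_city.graph, window)
        assert pct == 0.0 and avg == 0.0

    def test_saturates_beyond_graph_diameter(self, small_city):
        window = WalkWindow(duration=1e6, speed=1.5)
        pct, avg, counts = golden_window_coverage(
            small_city.event_xy, small_city.device_xy, small_city.graph, window)
        assert pct == 100.0
        assert avg == pytest.approx(len(small_city.devices))

    def test_route_coverage_never_exceeds_straight_coverage(self, small_city):
        # route >= straight distance, so route coverage is dominated
        budget = 270.0
        straight = benefit_profile(small_city.event_xy, small_city.device_xy,
                                   radii=[budget])
        pct, avg, _ = golden_window_coverage(
            small_city.event_xy, small_city.device_xy, small_city.graph,
            WalkWindow(duration=budget / 1.5, speed=1.5))
        assert pct <= straight.pct_covered[0] + 1e-9
        assert avg <= straight.avg_devices[0] + 1e-9


class TestFilterAvailable:
    @staticmethod
    def devices_df():
        return pd.DataFrame({
            "x": [0.0, 1.0, 2.0], "y": [0.0, 0.0, 0.0],
            "loc_type": ["community"] * 3,
            "available_from": ["06:00", "08:00", "06:00"],
            "available_to": ["19:00", "22:00", "18:00"],
        })

    def test_night_event_excludes_default_windows(self):
        out = filter_available(self.devices_df(), "2022-06-01 03:00")
        assert len(out) == 0

    def test_midday_event_keeps_all(self):
        out = filter_available(self.devices_df(), "2022-06-01 12:00")
        assert len(out) == 3

    def test_mixed_windows_match_brute_force(self):
        df = self.devices_df()
        out = filter_available(df, "2022-06-01 18:30")
        import datetime as dt
        t = dt.time(18, 30)
        expected = [i for i, row in df.iterrows()
                    if pd.Timestamp(f"1970-01-01 {row['available_from']}").time() <= t
                    <= pd.Timestamp(f"1970-01-01 {row['available_to']}").time()]
        assert list(out.index) == expected == [0, 1]

    def test_unparseable_window_names_record(self):
        df = self.devices_df()
        df.loc[1, "available_from"] = "not-a-time"
        with pytest.raises(ValueError, match="device 1"):
            filter_available(df, "2022-06-01 12:00")


class TestTypeCrossTable:
    @staticmethod
    def reference_frames():
        ev = pd.DataFrame({"loc_type": np.repeat(
            list(REFERENCE_TYPE_COUNTS),
            [c[0] for c in REFERENCE_TYPE_COUNTS.values()])})
        dv = pd.DataFrame({"loc_type": np.repeat(
            list(REFERENCE_TYPE_COUNTS),
            [c[1] for c in REFERENCE_TYPE_COUNTS.values()])})
        return ev, dv

    def test_community_share_is_78_4_percent(self):
        ev, dv = self.reference_frames()
        table = type_cross_table(ev, dv)
        assert table.loc["community", "event_count"] == 1058
        assert table.loc["community", "event_pct"] == pytest.approx(78.4, abs=0.05)

    def test_recomputed_percentages_match_printed_within_0_1(self):
        ev, dv = self.reference_frames()
        table = type_cross_table(ev, dv)
        for t, (ep, dp) in REFERENCE_TYPE_PCT.items():
            assert table.loc[t, "event_pct"] == pytest.approx(ep, abs=0.1)
            if table.loc[t, "device_count"] > 0:
                assert table.loc[t, "device_pct"] == pytest.approx(dp, abs=0.1)

    def test_percentages_sum_to_100(self):
        ev, dv = self.reference_frames()
        table = type_cross_table(ev, dv)
        assert table["event_pct"].sum() == pytest.approx(100.0)
        assert table["device_pct"].sum() == pytest.approx(100.0)

    def test_empty_events_rejected(self):
        with pytest.raises(ValueError):
            type_cross_table(pd.DataFrame({"loc_type": []}),
                             pd.DataFrame({"loc_type": ["school"]}))

    def test_unknown_type_listed(self):
        ev = pd.DataFrame({"loc_type": ["community", "moonbase"]})
        dv = pd.DataFrame({"loc_type": ["school"]})
        with pytest.raises(ValueError, match="moonbase"):
            type_cross_table(ev, dv, vocabulary=("community", "school"))
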