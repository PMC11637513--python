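"""Wind from-directions, radial distributions, and downwind-hour summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from downwind.geo_prep import Residence, RoadSegment
from downwind.wind_exposure import (
    PregnancyWindow,
    RadialDistribution,
    WindCoverageError,
    WindSeries,
    downwind_hours,
    pregnancy_hours,
    radial_distribution,
    summarize,
    wind_from_direction,
)


def _series_from_directions(directions, start="2010-01-01", speed=5.0):
    """Build an hourly WindSeries whose from-directions are ``directions``."""
    directions = np.asarray(directions, dtype=float)
    motion = np.radians((directions + 180.0) % 360.0)
    times = pd.date_range(start, periods=len(directions), freq="h")
    return WindSeries(times=times, u=speed * np.sin(motion), v=speed * np.cos(motion))


class TestFromDirection:
    @pytest.mark.parametrize(
        "u,v,expected",
        [
            (0.0, -1.0, 0.0),    # air moving due south = wind from north
            (-1.0, 0.0, 90.0),   # air moving due west = wind from east
            (0.0, 1.0, 180.0),
            (1.0, 0.0, 270.0),
            (1.0, 1.0, 225.0),
        ],
    )
    def test_axis_and_diagonal_cases(self, u, v, expected):
        assert wind_from_direction(u, v) == pytest.approx(expected)

    def test_calm_scalar_raises(self):
        with pytest.raises(ValueError):
            wind_from_direction(0.0, 0.0)

    def test_calm_vector_is_nan(self):
        out = wind_from_direction(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        assert np.isnan(out[0]) and out[1] == pytest.approx(225.0)

    def test_roundtrip_through_uv(self):
        dirs = np.arange(0.0, 360.0, 7.3)
        s = _series_from_directions(dirs)
        assert np.allclose(s.from_direction, dirs, atol=1e-9)


class TestPregnancyWindow:
    @pytest.mark.parametrize(
        "conception,birth,hours",
        [
            ("2010-05-01", "2010-05-01", 24),
            ("2010-05-01", "2010-05-02", 48),
            # 280-day gestation: inclusive-day count oracle, 281 days * 24 h
            ("2010-01-01", "2010-10-08", 281 * 24),
        ],
    )
    def test_inclusive_hour_count(self, conception, birth, hours):
        window = PregnancyWindow(conception, birth)
        assert pregnancy_hours(window) == hours
        # independent oracle: count calendar days inclusively
        days = (pd.Timestamp(birth) - pd.Timestamp(conception)).days + 1
        assert pregnancy_hours(window) == days * 24

    def test_birth_before_conception_raises(self):
        with pytest.raises(ValueError):
            PregnancyWindow("2010-05-01", "2010-04-30")


class TestRadialDistribution:
    def test_single_hour_marks_exactly_31_bins(self):
        s = _series_from_directions([90.0])
        window = PregnancyWindow("2010-01-01", "2010-01-01")
        rad = radial_distribution(window, s, min_coverage=0.0)
        assert rad.counts[75:106].tolist() == [1] * 31
        assert rad.counts.sum() == 31
        assert np.count_nonzero(rad.counts) == 31

    def test_window_wraps_around_north(self):
        s = _series_from_directions([5.0])
        rad = radial_distribution(
            PregnancyWindow("2010-01-01", "2010-01-01"), s, min_coverage=0.0
        )
        marked = set(np.flatnonzero(rad.counts))
        assert marked == {(5 + k) % 360 for k in range(-15, 16)}

    def test_all_calm_window_has_empty_bins(self):
        times = pd.date_range("2010-01-01", periods=24, freq="h")
        s = WindSeries(times=times, u=np.zeros(24), v=np.zeros(24))
        rad = radial_distribution(PregnancyWindow("2010-01-01", "2010-01-01"), s)
        assert rad.counts.sum() == 0
        assert rad.valid_hours == 0
        assert rad.m == 24

    def test_low_coverage_raises(self):
        s = _series_from_directions(np.zeros(24))
        with pytest.raises(WindCoverageError):
            radial_distribution(PregnancyWindow("2010-01-01", "2010-01-03"), s)

    @given(seed=st.integers(0, 10_000))
    def test_conservation_sum_is_31_per_valid_hour(self, seed):
        """For any wind draw, the 360 bins sum to 31x the non-calm hours."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(24, 24 * 14))
        dirs = rng.uniform(0, 360, n)
        s = _series_from_directions(dirs)
        calm = rng.random(n) < 0.1
        s.u[calm] = 0.0
        s.v[calm] = 0.0
        days = n // 24
        window = PregnancyWindow(
            "2011-01-01", pd.Timestamp("2011-01-01") + pd.Timedelta(days=days - 1)
        )
        s = WindSeries(times=pd.date_range("2011-01-01", periods=n, freq="h"), u=s.u, v=s.v)
        rad = radial_distribution(window, s, min_coverage=0.0)
        assert rad.counts.sum() == 31 * rad.valid_hours
        assert rad.valid_hours == int((~calm[: days * 24]).sum())


class TestDownwindHours:
    def _segments_at_bearings(self, residence, bearings, dist=100.0):
        segs = []
        for i, b in enumerate(bearings):
            rad = np.radians(b)
            mid = residence.location + dist * np.array([np.sin(rad), np.cos(rad)])
            along = np.array([np.cos(rad), -np.sin(rad)])  # perpendicular to sight line
            segs.append(
                RoadSegment(f"s{i}", "r", mid - 5 * along, mid + 5 * along, 10.0)
            )
        return segs

    def test_aligned_and_boundary_cases(self):
        res = Residence("R1", np.array([0.0, 0.0]))
        segs = self._segments_at_bearings(res, [0.0])
        aligned = _series_from_directions(np.zeros(100))
        rad = radial_distribution(
            PregnancyWindow("2010-01-01", "2010-01-05"), aligned, min_coverage=0.0
        )
        # 100 of the 120 window hours are present, all from due north
        assert downwind_hours(res, rad, segs)["s0"] == 100
        just_out = _series_from_directions(np.full(24, 20.0))
        rad = radial_distribution(
            PregnancyWindow("2010-01-01", "2010-01-01"), just_out
        )
        assert downwind_hours(res, rad, segs)["s0"] == 0
        at_edge = _series_from_directions(np.full(24, 15.0))
        rad = radial_distribution(PregnancyWindow("2010-01-01", "2010-01-01"), at_edge)
        assert downwind_hours(res, rad, segs)["s0"] == 24

    def test_coincident_segment_raises(self):
        res = Residence("R1", np.array([0.0, 0.0]))
        seg = RoadSegment("s", "r", np.array([-5.0, 0.0]), np.array([5.0, 0.0]), 10.0)
        rad = RadialDistribution(np.zeros(360, dtype=int), 0, 24)
        with pytest.raises(ValueError):
            downwind_hours(res, rad, [seg])

    def test_binned_hours_equal_per_hour_angular_oracle(self):
        """Integer-degree winds: bin lookup == brute-force per-hour test."""
        rng = np.random.default_rng(2024)
        for trial in range(10):
            res = Residence("R1", rng.uniform(-50, 50, 2))
            bearings = rng.uniform(0, 360, 25)
            segs = self._segments_at_bearings(res, bearings, dist=float(rng.uniform(50, 400)))
            dirs = rng.integers(0, 360, 5 * 24).astype(float)
            s = _series_from_directions(dirs, start="2012-03-01")
            window = PregnancyWindow("2012-03-01", "2012-03-05")
            rad = radial_distribution(window, s)
            got = downwind_hours(res, rad, segs)
            for seg in segs:
                vec = seg.midpoint - res.location
                bearing = np.degrees(np.arctan2(vec[0], vec[1])) % 360
                bearing = round(bearing) % 360
                diff = np.abs((dirs - bearing + 180) % 360 - 180)
                assert got[seg.segment_id] == int((diff <= 15).sum())

    @given(rotation=st.integers(0, 359))
    def test_rotation_equivariance(self, rotation):
        """Rotating winds and segment bearings together leaves d_li unchanged."""
        rng = np.random.default_rng(7)
        res = Residence("R1", np.array([0.0, 0.0]))
        bearings = rng.integers(0, 360, 10).astype(float)
        dirs = rng.integers(0, 360, 48).astype(float)
        window = PregnancyWindow("2012-03-01", "2012-03-02")

        def run(extra):
            segs = self._segments_at_bearings(res, (bearings + extra) % 360)
            s = _series_from_directions((dirs + extra) % 360, start="2012-03-01")
            rad = radial_distribution(window, s)
            return list(downwind_hours(res, rad, segs).values())

        assert run(0.0) == run(float(rotation))

    def test_mirror_residences_swap_under_wind_reversal(self):
        """Two residences on opposite sides of the same segment swap their
        percent-downwind when every wind direction is reversed."""
        seg = RoadSegment("s", "r", np.array([-5.0, 0.0]), np.array([5.0, 0.0]), 10.0)
        res_s = Residence("S", np.array([0.0, -80.0]))  # road is north of it
        res_n = Residence("N", np.array([0.0, 80.0]))
        rng = np.random.default_rng(5)
        dirs = rng.integers(0, 360, 72).astype(float)
        window = PregnancyWindow("2012-03-01", "2012-03-03")

        def pct(res, directions):
            s = _series_from_directions(directions, start="2012-03-01")
            rad = radial_distribution(window, s)
            d = downwind_hours(res, rad, [seg])
            return summarize(res, d, [seg], rad.m).pct_downwind_max

        assert pct(res_s, dirs) == pytest.approx(pct(res_n, (dirs + 180) % 360))
        assert pct(res_n, dirs) == pytest.approx(pct(res_s, (dirs + 180) % 360))


class TestSummarize:
    def _seg(self, sid, x, y):
        return RoadSegment(sid, "r", np.array([x - 5.0, y]), np.array([x + 5.0, y]), 10.0)

    def test_mean_max_and_percent(self):
        res = Residence("R1", np.array([0.0, 0.0]))
        segs = [self._seg("a", 0, 50), self._seg("b", 0, 100), self._seg("c", 0, 150)]
        s = summarize(res, {"a": 10, "b": 20, "c": 30}, segs, m=100)
        assert s.mean_hours == pytest.approx(20.0)
        assert s.max_road_hours == 30
        assert s.max_segment_id == "c"
        assert s.pct_downwind_max == pytest.approx(30.0)
        assert s.mean_pct_downwind == pytest.approx(20.0)

    def test_tie_broken_by_distance(self):
        res = Residence("R1", np.array([0.0, 0.0]))
        segs = [self._seg("far", 0, 60), self._seg("near", 0, 40)]
        s = summarize(res, {"far": 30, "near": 30}, segs, m=100)
        assert s.max_segment_id == "near"

    def test_all_zero_hours_picks_nearest(self):
        res = Residence("R1", np.array([0.0, 0.0]))
        segs = [self._seg("far", 0, 60), self._seg("near", 0, 40)]
        s = summarize(res, {"far": 0, "near": 0}, segs, m=100)
        assert s.mean_hours == 0.0
        assert s.pct_downwind_max == 0.0
        assert s.max_segment_id == "near"

    def test_zero_pregnancy_hours_raises(self):
        res = Residence("R1", np.array([0.0, 0.0]))
        with pytest.raises(ValueError):
            summarize(res, {"a": 1}, [self._seg("a", 0, 50)], m=0)


class TestWindSeriesIO:
    def test_csv_roundtrip(self, tmp_path):
        s = _series_from_directions(np.arange(48) % 360)
        path = tmp_path / "wind.csv"
        s.to_csv(path)
        back = WindSeries.from_csv(path)
        assert np.allclose(back.u, s.u) and np.allclose(back.v, s.v)
        assert (back.times == s.times).all()

    def test_netcdf_roundtrip_selects_nearest_cell(self, tmp_path):
        s = _series_from_directions(np.arange(24) % 360)
        path = tmp_path / "wind.nc"
        s.to_netcdf(path, lat=30.0, lon=-97.0)
        back = WindSeries.from_netcdf(path, lat=30.1, lon=-97.2)
        assert np.allclose(back.u, s.u) and np.allclose(back.v, s.v)
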