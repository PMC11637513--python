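"""Hourly wind vectors -> per-pregnancy radial distributions and downwind hours.

The exposure instrument is the direction the wind blows FROM, derived from
eastward/northward air-motion components (u, v).  For every pregnancy hour the
from-direction is rounded to the nearest integer degree j* and the 31 integer
bearing bins {j*-15 ... j*+15} (mod 360) are incremented: a road segment whose
bearing from the residence falls inside that +-15-degree window is upwind of
the residence for that hour, i.e. the residence is downwind of the segment.
Summing over the pregnancy gives a 360-bin radial distribution per residence;
joining segments to bins gives per-segment downwind hours d_li, their mean over
the n_i segments within 500 m, and the "max road": the segment upwind the most
hours, ties broken by proximity to the residence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geo_prep import Residence, RoadSegment, SegmentIndex

logger = logging.getLogger("downwind.wind")

#: Half-width (degrees) of the angular window; the full window spans 31 bins.
HALF_WINDOW_DEG: int = 15
#: Minimum fraction of pregnancy hours with wind data required to compute
#: a radial distribution.
MIN_WIND_COVERAGE: float = 0.95

_HOUR = pd.Timedelta(hours=1)


class WindCoverageError(ValueError):
    """Wind series covers too small a fraction of the pregnancy window."""


def wind_from_direction(u, v):
    """Meteorological from-direction (deg clockwise from north, [0, 360)).

    ``atan2(u, v)`` is the bearing the air moves TOWARD; the from-direction is
    its reverse.  Calm input (u = v = 0) is undefined: scalar calls raise,
    array calls return NaN at calm positions.
    """
    u_arr = np.asarray(u, dtype=float)
    v_arr = np.asarray(v, dtype=float)
    calm = (u_arr == 0) & (v_arr == 0)
    if u_arr.ndim == 0:
        if calm:
            raise ValueError("calm hour: wind direction undefined for u = v = 0")
        return float((math.degrees(math.atan2(u_arr, v_arr)) + 180.0) % 360.0)
    out = (np.degrees(np.arctan2(u_arr, v_arr)) + 180.0) % 360.0
    out[calm] = np.nan
    return out


@dataclass
class WindSeries:
    """A regular hourly u/v series; gaps are represented as NaN."""

    times: pd.DatetimeIndex
    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if not (len(self.times) == len(self.u) == len(self.v)):
            raise ValueError("times, u, v must have equal length")
        if len(self.times) > 1:
            steps = np.diff(self.times.asi8)
            if not (steps == steps[0]).all() or steps[0] != _HOUR.value:
                raise ValueError("WindSeries must be on a regular hourly grid")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def from_direction(self) -> np.ndarray:
        """From-direction per hour (deg); NaN for calm or missing hours."""
        return wind_from_direction(self.u, self.v)

    @property
    def direction_bins(self) -> np.ndarray:
        """Integer bearing bin per hour in {0..359}; -1 for calm/missing."""
        d = self.from_direction
        bins = np.full(len(d), -1, dtype=np.int32)
        ok = np.isfinite(d)
        bins[ok] = np.rint(d[ok]).astype(np.int32) % 360
        return bins

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "WindSeries":
        df = df.copy()
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        df = df.set_index("timestamp").sort_index()
        full = pd.date_range(df.index[0], df.index[-1], freq="h")
        df = df.reindex(full)
        return cls(times=full, u=df["u"].to_numpy(), v=df["v"].to_numpy())

    @classmethod
    def from_csv(cls, path: str | Path) -> "WindSeries":
        return cls.from_frame(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"timestamp": self.times, "u": self.u, "v": self.v}).to_csv(
            path, index=False
        )

    @classmethod
    def from_netcdf(
        cls,
        path: str | Path,
        lat: float | None = None,
        lon: float | None = None,
        u_var: str = "u10",
        v_var: str = "v10",
    ) -> "WindSeries":
        """Read an ERA5-like hourly u10/v10 file (NetCDF3, scipy engine).

        With a lat/lon grid the nearest grid cell to (lat, lon) is used — no
        spatial interpolation, mirroring the regional-wind design.
        """
        import xarray as xr

        ds = xr.open_dataset(path, engine="scipy")
        da_u, da_v = ds[u_var], ds[v_var]
        spatial = [d for d in da_u.dims if d not in ("time",)]
        if spatial:
            if lat is None or lon is None:
                raise ValueError("lat/lon required to select a grid cell")
            sel = {}
            for d in spatial:
                target = lat if d.startswith(("lat", "y")) else lon
                sel[d] = target
            da_u = da_u.sel(sel, method="nearest")
            da_v = da_v.sel(sel, method="nearest")
        times = pd.DatetimeIndex(pd.to_datetime(ds["time"].values))
        return cls.from_frame(
            pd.DataFrame(
                {"timestamp": times, "u": da_u.values, "v": da_v.values}
            )
        )

    def to_netcdf(self, path: str | Path, lat: float = 30.0, lon: float = -97.0) -> None:
        """Write a single-cell ERA5-like NetCDF3 file (scipy engine)."""
        import xarray as xr

        ds = xr.Dataset(
            {
                "u10": (("time", "latitude", "longitude"), self.u[:, None, None]),
                "v10": (("time", "latitude", "longitude"), self.v[:, None, None]),
            },
            coords={
                "time": self.times,
                "latitude": [lat],
                "longitude": [lon],
            },
        )
        ds.to_netcdf(path, engine="scipy")


@dataclass(frozen=True)
class PregnancyWindow:
    """Pregnancy interval: conception-day 00:00 through birth-day 23:00."""

    conception_date: pd.Timestamp
    birth_date: pd.Timestamp

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "conception_date", pd.Timestamp(self.conception_date).normalize()
        )
        object.__setattr__(self, "birth_date", pd.Timestamp(self.birth_date).normalize())
        if self.birth_date < self.conception_date:
            raise ValueError("birth_date precedes conception_date")

    @property
    def start(self) -> pd.Timestamp:
        return self.conception_date

    @property
    def end(self) -> pd.Timestamp:
        return self.birth_date + pd.Timedelta(hours=23)

    @property
    def hours(self) -> int:
        return (self.birth_date - self.conception_date).days * 24 + 24


def pregnancy_hours(window: PregnancyWindow) -> int:
    """Number of hourly instants in the pregnancy window (m_i), inclusive."""
    return window.hours


@dataclass
class RadialDistribution:
    """Per-residence 360-bin count of pregnancy hours by upwind bearing (d_ij)."""

    counts: np.ndarray  # length 360, window-smeared hour counts
    valid_hours: int
    m: int
    residence_id: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (360,):
            raise ValueError("counts must have length 360")


def _circular_window_sum(raw: np.ndarray, half_window: int) -> np.ndarray:
    """counts[j] = sum of raw over the circular window j-h .. j+h."""
    h = half_window
    padded = np.concatenate([raw[-h:], raw, raw[:h]])
    cs = np.concatenate([[0], np.cumsum(padded)])
    w = 2 * h + 1
    return cs[w:] - cs[:-w]


def _window_slice(window: PregnancyWindow, winds: WindSeries) -> tuple[int, int]:
    """Half-open index range of the series overlapping the pregnancy window."""
    i0 = int((window.start - winds.times[0]) / _HOUR)
    i1 = i0 + window.hours
    return max(i0, 0), min(i1, len(winds))


def radial_distribution(
    window: PregnancyWindow,
    winds: WindSeries,
    half_window: int = HALF_WINDOW_DEG,
    min_coverage: float = MIN_WIND_COVERAGE,
    residence_id: str | None = None,
) -> RadialDistribution:
    """360-bin distribution of pregnancy hours by wind from-direction.

    Each valid hour increments the ``2*half_window + 1`` bins centred on its
    rounded from-direction; calm and missing hours contribute to no bin but
    still count in m.  Raises :class:`WindCoverageError` when the series
    covers less than ``min_coverage`` of the window.
    """
    m = window.hours
    lo, hi = _window_slice(window, winds)
    bins = winds.direction_bins[lo:hi] if hi > lo else np.empty(0, dtype=np.int32)
    # presence = hours with finite u/v (calm hours are present but direction-less)
    present = int(np.isfinite(winds.u[lo:hi]).sum()) if hi > lo else 0
    if m > 0 and present / m < min_coverage:
        raise WindCoverageError(
            f"wind series covers {present}/{m} pregnancy hours "
            f"(< {min_coverage:.0%} required)"
        )
    valid = bins[bins >= 0]
    raw = np.bincount(valid, minlength=360)
    return RadialDistribution(
        counts=_circular_window_sum(raw, half_window),
        valid_hours=len(valid),
        m=m,
        residence_id=residence_id,
    )


def bearing_deg(origin: np.ndarray, target: np.ndarray) -> float:
    """Compass bearing (deg clockwise from north) from origin to target."""
    dx, dy = np.asarray(target, dtype=float) - np.asarray(origin, dtype=float)
    if dx == 0 and dy == 0:
        raise ValueError("bearing undefined: coincident points")
    return float(math.degrees(math.atan2(dx, dy)) % 360.0)


def downwind_hours(
    residence: Residence,
    dist: RadialDistribution,
    segments: Sequence[RoadSegment],
) -> dict[str, int]:
    """Hours downwind of each segment (d_li): radial-bin lookup at the
    integer bearing of the residence -> segment-midpoint direction."""
    out: dict[str, int] = {}
    for seg in segments:
        b = int(round(bearing_deg(residence.location, seg.midpoint))) % 360
        out[seg.segment_id] = int(dist.counts[b])
    return out


@dataclass
class DownwindSummary:
    """Per-residence downwind-hours summary over the within-500-m segments."""

    residence_id: str
    hours_per_segment: dict[str, int]
    mean_hours: float
    max_segment_id: str
    max_road_hours: int
    pct_downwind_max: float
    mean_pct_downwind: float
    m: int
    n_segments: int


def summarize(
    residence: Residence,
    hours_per_segment: Mapping[str, int],
    segments: Sequence[RoadSegment],
    m: int,
) -> DownwindSummary:
    """Mean downwind hours, max-upwind segment (ties -> nearest midpoint),
    and percent-of-pregnancy metrics for one residence."""
    if m <= 0:
        raise ValueError("pregnancy hours m must be > 0")
    if not hours_per_segment:
        raise ValueError("summarize needs at least one segment (n_i >= 1)")
    seg_by_id = {s.segment_id: s for s in segments}
    d = np.array([hours_per_segment[k] for k in hours_per_segment], dtype=float)
    ids = list(hours_per_segment)
    mean_hours = float(d.mean())
    dmax = d.max()
    ties = [i for i, v in enumerate(d) if v == dmax]
    if len(ties) > 1:
        dists = {
            i: float(np.hypot(*(seg_by_id[ids[i]].midpoint - residence.location)))
            for i in ties
        }
        best = min(ties, key=lambda i: (dists[i], ids[i]))
    else:
        best = ties[0]
    return DownwindSummary(
        residence_id=residence.residence_id,
        hours_per_segment=dict(hours_per_segment),
        mean_hours=mean_hours,
        max_segment_id=ids[best],
        max_road_hours=int(dmax),
        pct_downwind_max=100.0 * dmax / m,
        mean_pct_downwind=100.0 * mean_hours / m,
        m=m,
        n_segments=len(ids),
    )


def cohort_downwind_summaries(
    cohort: pd.DataFrame,
    winds: WindSeries,
    index: SegmentIndex,
    radius: float = 500.0,
    half_window: int = HALF_WINDOW_DEG,
    min_coverage: float = MIN_WIND_COVERAGE,
) -> pd.DataFrame:
    """Vectorised per-residence exposure summary for a whole cohort.

    ``cohort`` needs columns residence_id, x, y, conception_date, birth_date.
    Residences with no high-traffic segment midpoint within ``radius`` are
    dropped (they are outside the study population).  Returns one row per
    retained residence with the summary metrics plus the max-segment midpoint
    coordinates and the exact nearest-road distance (matching covariates and
    matching-score inputs).
    """
    xy = cohort[["x", "y"]].to_numpy(dtype=float)
    neighbors = index.neighbor_lists(xy, radius)
    bins_all = winds.direction_bins
    u_finite = np.isfinite(winds.u)
    t0 = winds.times[0]
    conc = pd.to_datetime(cohort["conception_date"]).dt.normalize()
    birth = pd.to_datetime(cohort["birth_date"]).dt.normalize()
    i0s = ((conc - t0) / _HOUR).astype(int).to_numpy()
    ms = ((birth - conc).dt.days * 24 + 24).to_numpy()

    rows = []
    n_dropped = 0
    mid = index.midpoints
    for r, (rid, nb) in enumerate(zip(cohort["residence_id"].to_numpy(), neighbors)):
        if not nb:
            n_dropped += 1
            continue
        nb = np.asarray(nb, dtype=int)
        vec = mid[nb] - xy[r]
        dist_mid = np.hypot(vec[:, 0], vec[:, 1])
        bearing_bins = np.rint(np.degrees(np.arctan2(vec[:, 0], vec[:, 1]))).astype(int) % 360
        m = int(ms[r])
        lo, hi = max(i0s[r], 0), min(i0s[r] + m, len(winds))
        present = int(u_finite[lo:hi].sum()) if hi > lo else 0
        if present / m < min_coverage:
            raise WindCoverageError(
                f"residence {rid}: wind covers {present}/{m} pregnancy hours"
            )
        b = bins_all[lo:hi]
        raw = np.bincount(b[b >= 0], minlength=360)
        counts = _circular_window_sum(raw, half_window)
        d = counts[bearing_bins]
        dmax = int(d.max())
        tie = d == dmax
        order = np.lexsort((nb[tie], dist_mid[tie]))
        best_local = np.flatnonzero(tie)[order[0]]
        best = nb[best_local]
        rows.append(
            {
                "residence_id": rid,
                "m": m,
                "valid_hours": int(raw.sum()),
                "n_segments": len(nb),
                "mean_hours": float(d.mean()),
                "max_segment_id": index.segments[best].segment_id,
                "max_road_hours": dmax,
                "pct_downwind_max": 100.0 * dmax / m,
                "mean_pct_downwind": 100.0 * d.mean() / m,
                "dist_to_max": float(dist_mid[best_local]),
                "max_mid_x": float(mid[best, 0]),
                "max_mid_y": float(mid[best, 1]),
                "nearest_road_distance": index.nearest_distance(xy[r]),
            }
        )
    if n_dropped:
        logger.info(
            "cohort_downwind_summaries: dropped %d residences with no "
            "high-traffic segment within %.0f m",
            n_dropped,
            radius,
        )
    return pd.DataFrame(rows)
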