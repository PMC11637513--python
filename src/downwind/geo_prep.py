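"""Road-network preparation: high-traffic selection, 10-m segmentation, proximity.

All geometry lives in a projected planar coordinate system with units of
meters; longitude/latitude inputs must be reprojected before they enter the
pipeline.  Roads are polylines carrying annual average daily traffic (AADT)
counts per calendar year; roads at or above 25,000 vehicles/day are
"high-traffic" and are diced into 10-m segments, the elementary line sources
of the wind-exposure analysis.  Residences enter the cohort when at least one
high-traffic segment midpoint lies within 500 m.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import LineString, mapping, shape

logger = logging.getLogger("downwind.geo")

#: AADT (vehicles/day) at or above which a road counts as high-traffic.
HIGH_TRAFFIC_AADT: float = 25_000.0
#: Length (m) of the elementary road segments.
DEFAULT_SEGMENT_LENGTH: float = 10.0
#: Cohort-inclusion radius (m) around high-traffic segments.
NEAR_ROAD_RADIUS: float = 500.0

_LENGTH_TOL = 1e-6


class CRSMismatchError(ValueError):
    """Raised when two layers carry incompatible coordinate-system labels."""


class MissingAADTError(KeyError):
    """Raised when a road has no usable AADT value for the requested year."""


def _check_crs(a: str | None, b: str | None) -> None:
    if a is not None and b is not None and a != b:
        raise CRSMismatchError(f"coordinate systems differ: {a!r} vs {b!r}")


@dataclass
class Road:
    """A road polyline with per-year AADT attributes (planar meters)."""

    road_id: str
    coords: np.ndarray  # (n, 2) vertex array
    aadt_by_year: dict[int, float] = field(default_factory=dict)
    crs: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[0] < 2 or self.coords.shape[1] != 2:
            raise ValueError(f"road {self.road_id}: polyline needs >= 2 (x, y) vertices")
        if any(v < 0 for v in self.aadt_by_year.values()):
            raise ValueError(f"road {self.road_id}: AADT values must be >= 0")

    @property
    def line(self) -> LineString:
        return LineString(self.coords)

    @property
    def length(self) -> float:
        return float(self.line.length)


@dataclass
class RoadSegment:
    """A ~10-m piece of a high-traffic road, represented by its chord.

    ``length`` is the arc length of the parent polyline between the cut
    points, so segment lengths of one road always sum to the polyline length;
    ``midpoint`` is the chord midpoint, the reference point for radial joins.
    """

    segment_id: str
    parent_road_id: str
    start: np.ndarray
    end: np.ndarray
    length: float

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.end = np.asarray(self.end, dtype=float)

    @property
    def midpoint(self) -> np.ndarray:
        return (self.start + self.end) / 2.0


@dataclass
class Residence:
    """A maternal residence location (planar meters)."""

    residence_id: str
    location: np.ndarray
    birth_record_id: str | None = None
    crs: str | None = None

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, dtype=float)


def aadt_for_year(road: Road, year: int, carry_forward: bool = True) -> float:
    """AADT for ``year``, carrying the nearest prior year forward if allowed."""
    if year in road.aadt_by_year:
        return road.aadt_by_year[year]
    if carry_forward:
        prior = [y for y in road.aadt_by_year if y < year]
        if prior:
            y0 = max(prior)
            logger.info("road %s: no AADT for %d, carrying %d forward", road.road_id, year, y0)
            return road.aadt_by_year[y0]
    raise MissingAADTError(f"road {road.road_id} has no AADT for year {year}")


def filter_high_traffic(
    roads: Iterable[Road],
    year: int,
    threshold: float = HIGH_TRAFFIC_AADT,
    carry_forward: bool = True,
) -> list[Road]:
    """Roads with AADT >= ``threshold`` in ``year`` (inclusive comparison)."""
    return [r for r in roads if aadt_for_year(r, year, carry_forward) >= threshold]


def segment_road(road: Road, segment_length: float = DEFAULT_SEGMENT_LENGTH) -> list[RoadSegment]:
    """Tile a road polyline into ordered segments of ``segment_length`` meters.

    All pieces have the nominal arc length except possibly the last, which
    keeps the remainder (dropping it would delete road ends near residences).
    """
    if segment_length <= 0:
        raise ValueError("segment_length must be > 0")
    line = road.line
    total = float(line.length)
    if total <= _LENGTH_TOL:
        raise ValueError(f"road {road.road_id}: degenerate zero-length polyline")
    cuts = list(np.arange(0.0, total, segment_length))
    if total - cuts[-1] > _LENGTH_TOL:
        cuts.append(total)
    else:
        cuts[-1] = total
    pts = [line.interpolate(c) for c in cuts]
    segments = []
    for k in range(len(cuts) - 1):
        segments.append(
            RoadSegment(
                segment_id=f"{road.road_id}:{k:05d}",
                parent_road_id=road.road_id,
                start=np.array([pts[k].x, pts[k].y]),
                end=np.array([pts[k + 1].x, pts[k + 1].y]),
                length=cuts[k + 1] - cuts[k],
            )
        )
    return segments


def segment_roads(
    roads: Iterable[Road], segment_length: float = DEFAULT_SEGMENT_LENGTH
) -> list[RoadSegment]:
    out: list[RoadSegment] = []
    for road in roads:
        out.extend(segment_road(road, segment_length))
    return out


def point_segment_distances(point: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Euclidean distance from one point to each segment chord."""
    p = np.asarray(point, dtype=float)
    d = ends - starts
    lensq = np.einsum("ij,ij->i", d, d)
    t = np.zeros(len(starts))
    nz = lensq > 0
    t[nz] = np.einsum("ij,ij->i", (p - starts)[nz], d[nz]) / lensq[nz]
    t = np.clip(t, 0.0, 1.0)
    proj = starts + t[:, None] * d
    return np.hypot(*(p - proj).T)


class SegmentIndex:
    """KD-tree over segment midpoints with exact point-to-segment queries."""

    def __init__(self, segments: Sequence[RoadSegment], crs: str | None = None):
        segments = list(segments)
        if not segments:
            raise ValueError("SegmentIndex needs at least one segment")
        self.segments = segments
        self.crs = crs
        self.midpoints = np.array([s.midpoint for s in segments])
        self.starts = np.array([s.start for s in segments])
        self.ends = np.array([s.end for s in segments])
        self.max_length = max(s.length for s in segments)
        self._tree = cKDTree(self.midpoints)

    def __len__(self) -> int:
        return len(self.segments)

    def within_indices(self, point: np.ndarray, radius: float) -> list[int]:
        """Indices of segments whose MIDPOINT lies within ``radius`` of point."""
        return sorted(self._tree.query_ball_point(np.asarray(point, dtype=float), radius))

    def within(self, point: np.ndarray, radius: float) -> list[RoadSegment]:
        return [self.segments[i] for i in self.within_indices(point, radius)]

    def neighbor_lists(self, points: np.ndarray, radius: float) -> list[list[int]]:
        """Vectorised ``within_indices`` for an (n, 2) array of points."""
        return self._tree.query_ball_point(np.asarray(points, dtype=float), radius)

    def nearest_distance(self, point: np.ndarray) -> float:
        """Exact minimum point-to-segment distance over all segments."""
        point = np.asarray(point, dtype=float)
        d_mid, _ = self._tree.query(point)
        # the true nearest segment's midpoint is within d_mid + half a chord
        cand = self._tree.query_ball_point(point, d_mid + self.max_length)
        cand = np.asarray(cand, dtype=int)
        return float(point_segment_distances(point, self.starts[cand], self.ends[cand]).min())

    def nearest_distances(self, points: np.ndarray) -> np.ndarray:
        return np.array([self.nearest_distance(p) for p in np.asarray(points, dtype=float)])


def segments_within(
    residence: Residence,
    index: SegmentIndex,
    radius: float = NEAR_ROAD_RADIUS,
) -> list[RoadSegment]:
    """Segments whose midpoint is within ``radius`` m of the residence (n_i set)."""
    _check_crs(residence.crs, index.crs)
    return index.within(residence.location, radius)


def nearest_road_distance(
    residence: Residence, segments: SegmentIndex | Sequence[RoadSegment]
) -> float:
    """Minimum point-to-segment distance (m) from residence to any segment."""
    if isinstance(segments, SegmentIndex):
        _check_crs(residence.crs, segments.crs)
        return segments.nearest_distance(residence.location)
    segments = list(segments)
    if not segments:
        raise ValueError("nearest_road_distance: empty segment set")
    starts = np.array([s.start for s in segments])
    ends = np.array([s.end for s in segments])
    return float(point_segment_distances(residence.location, starts, ends).min())


# ---------------------------------------------------------------------------
# GeoJSON I/O (planar coordinates; AADT carried as ``aadt_<year>`` properties)
# ---------------------------------------------------------------------------

def roads_to_geojson(roads: Iterable[Road], path: str | Path | None = None) -> dict:
    features = []
    for r in roads:
        props = {"road_id": r.road_id}
        for year, v in sorted(r.aadt_by_year.items()):
            props[f"aadt_{year}"] = float(v)
        features.append(
            {"type": "Feature", "geometry": mapping(r.line), "properties": props}
        )
    fc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(fc))
    return fc


def roads_from_geojson(src: str | Path | Mapping) -> list[Road]:
    fc = json.loads(Path(src).read_text()) if not isinstance(src, Mapping) else src
    roads = []
    for feat in fc["features"]:
        geom = shape(feat["geometry"])
        props = feat.get("properties", {})
        aadt = {
            int(k.split("_", 1)[1]): float(v)
            for k, v in props.items()
            if k.startswith("aadt_")
        }
        roads.append(
            Road(
                road_id=str(props.get("road_id", f"road{len(roads)}")),
                coords=np.asarray(geom.coords),
                aadt_by_year=aadt,
            )
        )
    return roads


def segments_to_geojson(
    segments: Iterable[RoadSegment], path: str | Path | None = None
) -> dict:
    features = [
        {
            "type": "Feature",
            "geometry": {
                "type": "LineString",
                "coordinates": [list(s.start), list(s.end)],
            },
            "properties": {
                "segment_id": s.segment_id,
                "parent_road_id": s.parent_road_id,
                "length": s.length,
            },
        }
        for s in segments
    ]
    fc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(fc))
    return fc
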