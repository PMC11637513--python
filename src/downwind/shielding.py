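"""Building/tree shielding: percent of the residence-segment region covered.

The "between" region for a (residence, road segment) pair is the triangle
spanned by the segment endpoints and the residence; the shielding fraction is
the percent of that triangle's area covered by the union of footprints of one
kind (building or tree).  Union semantics mean stacked footprints are never
double-counted.  Shielding enters the epidemiological models only as an
adjustment covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from shapely.geometry import Polygon, mapping, shape
from shapely.ops import unary_union

from .geo_prep import Residence, RoadSegment

logger = logging.getLogger("downwind.shielding")

_AREA_TOL = 1e-9


@dataclass
class Footprint:
    """A building or tree-canopy footprint polygon (planar meters)."""

    footprint_id: str
    polygon: Polygon
    kind: str = "building"  # "building" | "tree"

    def __post_init__(self) -> None:
        if not self.polygon.is_valid:
            raise ValueError(f"footprint {self.footprint_id}: invalid polygon")
        if self.polygon.area <= 0:
            raise ValueError(f"footprint {self.footprint_id}: zero-area polygon")


def between_region(residence: Residence, segment: RoadSegment) -> Polygon:
    """Triangle (segment.start, segment.end, residence); may be degenerate."""
    return Polygon(
        [tuple(segment.start), tuple(segment.end), tuple(residence.location)]
    )


def shielding_fraction(
    residence: Residence,
    segment: RoadSegment,
    footprints: Iterable[Footprint],
    kind: str = "building",
) -> float:
    """Percent of the between-region covered by kind-matching footprints."""
    region = between_region(residence, segment)
    if region.area <= _AREA_TOL:
        logger.warning(
            "degenerate between-region for residence %s / segment %s; shielding = 0",
            residence.residence_id,
            segment.segment_id,
        )
        return 0.0
    polys = [f.polygon for f in footprints if f.kind == kind]
    if not polys:
        return 0.0
    covered = region.intersection(unary_union(polys)).area
    return 100.0 * covered / region.area


def max_road_shielding(
    summary,
    residence: Residence,
    segments_by_id: Mapping[str, RoadSegment],
    footprints: Sequence[Footprint],
) -> tuple[float, float]:
    """(building %, tree %) against the residence's max-upwind segment."""
    seg = segments_by_id[summary.max_segment_id]
    return (
        shielding_fraction(residence, seg, footprints, kind="building"),
        shielding_fraction(residence, seg, footprints, kind="tree"),
    )


def footprints_to_geojson(
    footprints: Iterable[Footprint], path: str | Path | None = None
) -> dict:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(f.polygon),
                "properties": {"footprint_id": f.footprint_id, "kind": f.kind},
            }
            for f in footprints
        ],
    }
    if path is not None:
        Path(path).write_text(json.dumps(fc))
    return fc


def footprints_from_geojson(src: str | Path | Mapping) -> list[Footprint]:
    fc = json.loads(Path(src).read_text()) if not isinstance(src, Mapping) else src
    out = []
    for i, feat in enumerate(fc["features"]):
        props = feat.get("properties", {})
        out.append(
            Footprint(
                footprint_id=str(props.get("footprint_id", f"fp{i}")),
                polygon=shape(feat["geometry"]),
                kind=str(props.get("kind", "building")),
            )
        )
    return out
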