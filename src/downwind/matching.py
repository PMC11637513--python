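"""Exposed/control assignment and greedy geographic matching.

Residences in the top quartile of max-road downwind hours are "exposed"
(predominantly downwind) and the bottom quartile are "controls" (predominantly
upwind).  Each exposed residence is matched with up to 4 controls by a
meters-scale match score:

    locality score  = |dist(exposed, max seg of exposed) - dist(control, same seg)|
    near-road score = |nearest-road dist(exposed) - nearest-road dist(control)|
    match score     = locality + near-road + 10 * |birth year difference|

Candidates are rejected outright when birth years differ by more than 4, and a
pair is includable only when BOTH the locality and near-road scores are
strictly below the inclusion threshold (default 100 m).  Assignment is greedy
over all includable candidates in ascending match-score order; by default a
control serves at most one exposed residence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger("downwind.matching")

INCLUSION_THRESHOLD_M: float = 100.0
MAX_CONTROLS: int = 4
YEAR_WINDOW: int = 4
YEAR_PENALTY_WEIGHT: float = 10.0


@dataclass(frozen=True)
class MatchCandidate:
    """A scored exposed/control pairing."""

    exposed_id: str
    control_id: str
    locality_score: float
    near_road_score: float
    year_penalty: float
    match_score: float
    includable: bool


@dataclass
class MatchedSet:
    """One exposed residence with its accepted controls (at most 4)."""

    exposed_id: str
    control_ids: list[str] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)


def assign_groups(max_road_hours: pd.Series) -> pd.Series:
    """Quartile-based exposure groups over the full within-500-m cohort.

    Top quartile (>= 75th percentile, inclusive) -> "exposed"; bottom quartile
    (<= 25th percentile) -> "control"; the rest "unassigned".  Percentiles use
    the linear-interpolation definition.  Raises when the quartiles are
    degenerate (all values identical).
    """
    vals = max_road_hours.to_numpy(dtype=float)
    if len(vals) < 4:
        raise ValueError("assign_groups needs at least 4 residences")
    q25, q75 = np.quantile(vals, [0.25, 0.75])
    if q75 <= q25:
        raise ValueError("degenerate quartiles: max-road hours nearly constant")
    groups = pd.Series("unassigned", index=max_road_hours.index, dtype=object)
    groups[max_road_hours >= q75] = "exposed"
    groups[max_road_hours <= q25] = "control"
    return groups


def score_pair(
    dist_maxee: float,
    dist_maxec: float,
    dist_neare: float,
    dist_nearc: float,
    year_e: int,
    year_c: int,
    exposed_id: str = "e",
    control_id: str = "c",
    year_window: int = YEAR_WINDOW,
    threshold: float = INCLUSION_THRESHOLD_M,
) -> MatchCandidate | None:
    """Score one exposed/control pairing; None when the year rule fails."""
    dy = abs(int(year_e) - int(year_c))
    if dy > year_window:
        return None
    locality = abs(dist_maxee - dist_maxec)
    near = abs(dist_neare - dist_nearc)
    penalty = YEAR_PENALTY_WEIGHT * dy
    return MatchCandidate(
        exposed_id=exposed_id,
        control_id=control_id,
        locality_score=locality,
        near_road_score=near,
        year_penalty=penalty,
        match_score=locality + near + penalty,
        includable=locality < threshold and near < threshold,
    )


def passes_inclusion(c: MatchCandidate, threshold: float = INCLUSION_THRESHOLD_M) -> bool:
    """Strict-inequality inclusion test on both score components."""
    return c.locality_score < threshold and c.near_road_score < threshold


def build_matches(
    candidates: Sequence[MatchCandidate],
    max_controls: int = MAX_CONTROLS,
    threshold: float = INCLUSION_THRESHOLD_M,
    allow_control_reuse: bool = False,
) -> list[MatchedSet]:
    """Greedy global assignment of controls to exposed residences.

    All includable candidates are sorted by ascending match score (ties:
    smaller locality score, then stable input order); a candidate is accepted
    iff its exposed member holds fewer than ``max_controls`` controls and (by
    default) its control member is still unused.
    """
    order = sorted(
        (c for c in candidates if passes_inclusion(c, threshold)),
        key=lambda c: (c.match_score, c.locality_score),
    )
    sets: dict[str, MatchedSet] = {}
    used_controls: set[str] = set()
    for c in order:
        if not allow_control_reuse and c.control_id in used_controls:
            continue
        s = sets.get(c.exposed_id)
        if s is not None and len(s.control_ids) >= max_controls:
            continue
        if s is None:
            s = sets[c.exposed_id] = MatchedSet(exposed_id=c.exposed_id)
        s.control_ids.append(c.control_id)
        s.scores.append(c.match_score)
        used_controls.add(c.control_id)
    return list(sets.values())


def match_cohort(
    cohort: pd.DataFrame,
    threshold: float = INCLUSION_THRESHOLD_M,
    max_controls: int = MAX_CONTROLS,
    year_window: int = YEAR_WINDOW,
    allow_control_reuse: bool = False,
    restrict_weeks: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Full matching pass over a cohort summary frame.

    ``cohort`` needs columns: residence_id, x, y, birth_year, max_road_hours,
    dist_to_max, max_mid_x, max_mid_y, nearest_road_distance (and
    gestational_weeks when ``restrict_weeks`` is given; the restriction is
    applied BEFORE group assignment and matching, as required for the
    term-birth-weight cohort).

    Returns ``(matches, groups)``: one row per accepted exposed/control pair
    with its score components, and the exposure-group label per residence.
    """
    df = cohort.reset_index(drop=True)
    if restrict_weeks is not None:
        lo, hi = restrict_weeks
        df = df[(df["gestational_weeks"] >= lo) & (df["gestational_weeks"] <= hi)]
        df = df.reset_index(drop=True)
    groups = assign_groups(df.set_index("residence_id")["max_road_hours"])
    df = df.assign(group=groups.to_numpy())
    exposed = df[df["group"] == "exposed"].reset_index(drop=True)
    control = df[df["group"] == "control"].reset_index(drop=True)
    if exposed.empty or control.empty:
        return _empty_matches(), groups

    c_xy = control[["x", "y"]].to_numpy(dtype=float)
    c_near = control["nearest_road_distance"].to_numpy(dtype=float)
    c_year = control["birth_year"].to_numpy(dtype=int)
    tree = cKDTree(c_xy)

    e_mid = exposed[["max_mid_x", "max_mid_y"]].to_numpy(dtype=float)
    e_dmax = exposed["dist_to_max"].to_numpy(dtype=float)
    e_near = exposed["nearest_road_distance"].to_numpy(dtype=float)
    e_year = exposed["birth_year"].to_numpy(dtype=int)

    # a candidate control must sit within dist_maxee + threshold of the
    # exposed residence's max segment midpoint, otherwise locality >= threshold
    cand_lists = tree.query_ball_point(e_mid, e_dmax + threshold)
    ei, ci = [], []
    for i, lst in enumerate(cand_lists):
        if lst:
            ei.append(np.full(len(lst), i, dtype=np.int64))
            ci.append(np.asarray(lst, dtype=np.int64))
    if not ei:
        return _empty_matches(), groups
    ei = np.concatenate(ei)
    ci = np.concatenate(ci)

    dist_maxec = np.hypot(
        c_xy[ci, 0] - e_mid[ei, 0], c_xy[ci, 1] - e_mid[ei, 1]
    )
    locality = np.abs(e_dmax[ei] - dist_maxec)
    near = np.abs(e_near[ei] - c_near[ci])
    dyear = np.abs(e_year[ei] - c_year[ci])
    keep = (locality < threshold) & (near < threshold) & (dyear <= year_window)
    ei, ci = ei[keep], ci[keep]
    locality, near, dyear = locality[keep], near[keep], dyear[keep]
    penalty = YEAR_PENALTY_WEIGHT * dyear
    score = locality + near + penalty

    order = np.lexsort((np.arange(len(score)), locality, score))
    counts = np.zeros(len(exposed), dtype=np.int64)
    used = np.zeros(len(control), dtype=bool)
    rows = []
    e_ids = exposed["residence_id"].to_numpy()
    c_ids = control["residence_id"].to_numpy()
    for k in order:
        e, c = ei[k], ci[k]
        if counts[e] >= max_controls:
            continue
        if not allow_control_reuse and used[c]:
            continue
        counts[e] += 1
        used[c] = True
        rows.append(
            {
                "exposed_id": e_ids[e],
                "control_id": c_ids[c],
                "locality_score": float(locality[k]),
                "near_road_score": float(near[k]),
                "year_penalty": float(penalty[k]),
                "match_score": float(score[k]),
            }
        )
    matches = pd.DataFrame(rows) if rows else _empty_matches()
    if not matches.empty:
        matches = matches.sort_values(
            ["exposed_id", "match_score"], kind="stable"
        ).reset_index(drop=True)
        matches["set_id"] = matches["exposed_id"]
    logger.info(
        "matched %d pairs (%d exposed, median %.0f controls/exposed)",
        len(matches),
        matches["exposed_id"].nunique() if not matches.empty else 0,
        matches.groupby("exposed_id").size().median() if not matches.empty else 0,
    )
    return matches, groups


def _empty_matches() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "exposed_id",
            "control_id",
            "locality_score",
            "near_road_score",
            "year_penalty",
            "match_score",
            "set_id",
        ]
    )


def balance_table(
    matches: pd.DataFrame,
    records: pd.DataFrame,
    columns: Iterable[str],
) -> pd.DataFrame:
    """Descriptive exposed-vs-control comparison over matched individuals.

    ``records`` must be indexed by residence_id.  Numeric columns are averaged;
    the first row reports group sizes.
    """
    if matches.empty:
        raise ValueError("balance_table needs non-empty matches")
    exposed_ids = matches["exposed_id"].unique()
    control_ids = matches["control_id"].unique()
    out = {}
    for label, ids in (("downwind", exposed_ids), ("upwind", control_ids)):
        sub = records.loc[records.index.intersection(ids)]
        col = {"n": float(len(sub))}
        for c in columns:
            col[c] = float(pd.to_numeric(sub[c]).mean())
        out[label] = col
    table = pd.DataFrame(out)
    table["difference"] = table["downwind"] - table["upwind"]
    return table
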