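"""Synthetic study system: roads, wind, residences, footprints, birth cohorts.

The generator emulates the inputs the analysis assumes: a road network with
per-year AADT (a configurable share above the 25,000 vehicles/day high-traffic
threshold), an hourly u/v wind series with a prevailing from-direction (von
Mises directions, gamma speeds), residences scattered on BOTH sides of the
high-traffic roads within the 500-m study band, rectangular building/tree
footprints, and birth records whose outcomes carry a configurable true
downwind effect.

Effects are injected on TRUE computed exposure (the residence's
percent-of-pregnancy downwind of its max road, thresholded at the cohort
median), not on matched-group labels, so the whole chain — exposure
assessment, matching, regression — is exercised when recovering them.
Covariates are drawn with no dependence on wind side (instrument validity by
construction); an optional confounding switch correlates covariates and an
unmeasured disadvantage term with road distance, which biases naive
near/far-road comparisons but not the matched upwind/downwind contrast.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geo_prep, shielding, wind_exposure
from .geo_prep import Road, SegmentIndex
from .shielding import Footprint
from .wind_exposure import WindSeries

logger = logging.getLogger("downwind.synth")

#: Gestational-age distribution (completed weeks 22-42); roughly 9% preterm
#: and 1.4% very preterm, as in large US birth cohorts.
DEFAULT_GESTATION_WEIGHTS: dict[int, float] = {
    22: 0.0008, 23: 0.0009, 24: 0.0010, 25: 0.0011, 26: 0.0012, 27: 0.0014,
    28: 0.0018, 29: 0.0022, 30: 0.0028, 31: 0.0038, 32: 0.0050, 33: 0.0070,
    34: 0.0110, 35: 0.0180, 36: 0.0330, 37: 0.0640, 38: 0.1650, 39: 0.2900,
    40: 0.2550, 41: 0.1150, 42: 0.0410,
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study system (one master seed)."""

    seed: int = 0
    # roads
    n_roads: int = 3
    road_length_m: float = 8000.0
    road_spacing_m: float = 1500.0
    road_aadt_range: tuple[float, float] = (5_000.0, 120_000.0)
    high_traffic_share: float = 0.7
    curved_share: float = 0.5
    # residences; offsets mix a near-road-skewed Beta(1, b) component with a
    # uniform tail, emulating development clustering along arterial corridors
    n_residences: int = 2000
    residence_band: float = 500.0
    residence_min_offset: float = 10.0
    offset_near_share: float = 0.75
    offset_beta_b: float = 8.0
    # calendar
    study_years: tuple[int, int] = (2007, 2016)
    # wind
    wind_prevailing_direction: float = 0.0  # degrees, from-direction
    wind_concentration: float = 1.5  # von Mises kappa
    wind_speed_shape: float = 2.0
    wind_speed_scale: float = 2.5  # gamma; mean speed = shape*scale m/s
    calm_fraction: float = 0.01
    # footprints
    building_density: float = 40.0  # footprints per km^2
    tree_share: float = 0.3
    # outcome model
    effect_tbw_downwind: float = -30.0  # grams
    effect_decay_length: float | None = None  # meters; None = homogeneous
    effect_logodds: dict[str, float] = field(
        default_factory=lambda: {"ptb": 0.0, "vptb": 0.0}
    )
    effect_tbw_modifier: tuple[str, dict] | None = None  # (column, level -> grams)
    baseline_tbw_mean: float = 3300.0
    baseline_tbw_sd: float = 450.0
    grams_per_week: float = 140.0
    gestation_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_GESTATION_WEIGHTS)
    )
    # confounding switch
    confounding: bool = False
    confound_tbw: float = -80.0  # grams per unit of (1 - d/500)
    confound_smoking_logodds: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = dict(raw)
        for key in ("road_aadt_range", "study_years", "effect_tbw_modifier"):
            if key in kw and kw[key] is not None:
                kw[key] = tuple(kw[key])
        if "gestation_weights" in kw and kw["gestation_weights"] is not None:
            kw["gestation_weights"] = {int(k): float(v) for k, v in kw["gestation_weights"].items()}
        return cls(**kw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["road_aadt_range"] = list(d["road_aadt_range"])
        d["study_years"] = list(d["study_years"])
        if d["effect_tbw_modifier"] is not None:
            d["effect_tbw_modifier"] = list(d["effect_tbw_modifier"])
        Path(path).write_text(yaml.safe_dump(d))


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def gen_roads(config: SimulationConfig, rng: np.random.Generator | None = None) -> list[Road]:
    """Parallel east-west roads (straight or gently curved) with per-year AADT."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo, hi = config.road_aadt_range
    hi = max(hi, geo_prep.HIGH_TRAFFIC_AADT + 1)
    roads = []
    x = np.linspace(0.0, config.road_length_m, max(int(config.road_length_m / 100), 2))
    for i in range(config.n_roads):
        y0 = i * config.road_spacing_m
        if rng.random() < config.curved_share:
            amp = rng.uniform(10.0, 40.0)
            wavelength = rng.uniform(2000.0, 5000.0)
            y = y0 + amp * np.sin(2 * np.pi * x / wavelength)
        else:
            y = np.full_like(x, y0)
        high = rng.random() < config.high_traffic_share
        if high:
            base = rng.uniform(geo_prep.HIGH_TRAFFIC_AADT, hi)
        else:
            base = rng.uniform(lo, geo_prep.HIGH_TRAFFIC_AADT - 1)
        aadt = {}
        for year in range(config.study_years[0], config.study_years[1] + 1):
            jitter = rng.uniform(0.97, 1.03)
            v = base * jitter
            # yearly jitter must not flip the road across the threshold
            if high:
                v = max(v, geo_prep.HIGH_TRAFFIC_AADT)
            else:
                v = min(v, geo_prep.HIGH_TRAFFIC_AADT - 1)
            aadt[year] = float(v)
        roads.append(Road(road_id=f"road{i:03d}", coords=np.column_stack([x, y]), aadt_by_year=aadt))
    return roads


def gen_wind(
    config: SimulationConfig,
    start: pd.Timestamp,
    end: pd.Timestamp,
    rng: np.random.Generator | None = None,
) -> WindSeries:
    """Hourly series: from-directions ~ von Mises, speeds ~ gamma."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    times = pd.date_range(start, end, freq="h")
    n = len(times)
    if n == 0:
        raise ValueError("gen_wind: start must precede end")
    if config.wind_concentration > 0:
        dirs = np.degrees(rng.vonmises(0.0, config.wind_concentration, n))
    else:
        dirs = rng.uniform(-180.0, 180.0, n)
    dirs = (dirs + config.wind_prevailing_direction) % 360.0
    speed = rng.gamma(config.wind_speed_shape, config.wind_speed_scale, n)
    motion = np.radians((dirs + 180.0) % 360.0)
    u = speed * np.sin(motion)
    v = speed * np.cos(motion)
    calm = rng.random(n) < config.calm_fraction
    u[calm] = 0.0
    v[calm] = 0.0
    return WindSeries(times=times, u=u, v=v)


def gen_residences(
    config: SimulationConfig,
    roads: list[Road],
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, list[Footprint]]:
    """Residences on both sides of high-traffic roads + scattered footprints.

    Offsets are uniform over (min_offset, residence_band) meters perpendicular
    to the road, sides balanced ~50/50.  Returns (residences, footprints);
    residences carry the generating road, side (+1 north / -1 south) and
    offset for diagnostics.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    year = config.study_years[0]
    high = geo_prep.filter_high_traffic(roads, year)
    if not high:
        raise ValueError("gen_residences: no high-traffic roads")
    rows = []
    for i in range(config.n_residences):
        road = high[rng.integers(len(high))]
        line = road.line
        t = rng.uniform(0.0, line.length)
        p = line.interpolate(t)
        p2 = line.interpolate(min(t + 1.0, line.length))
        tangent = np.array([p2.x - p.x, p2.y - p.y])
        nrm = np.hypot(*tangent)
        tangent = tangent / nrm if nrm > 0 else np.array([1.0, 0.0])
        normal = np.array([-tangent[1], tangent[0]])  # points "left"/north for W->E roads
        side = 1 if rng.random() < 0.5 else -1
        span = config.residence_band - config.residence_min_offset
        if rng.random() < config.offset_near_share:
            frac = rng.beta(1.0, config.offset_beta_b)
        else:
            frac = rng.random()
        offset = config.residence_min_offset + span * frac
        xy = np.array([p.x, p.y]) + side * offset * normal
        rows.append(
            {
                "residence_id": f"R{i:06d}",
                "birth_record_id": f"B{i:06d}",
                "x": xy[0],
                "y": xy[1],
                "road_id": road.road_id,
                "side": side * int(np.sign(normal[1]) or 1),
                "offset": offset,
            }
        )
    residences = pd.DataFrame(rows)

    xs = residences["x"]
    ys = residences["y"]
    x0, x1 = xs.min() - 500, xs.max() + 500
    y0, y1 = ys.min() - 500, ys.max() + 500
    area_km2 = (x1 - x0) * (y1 - y0) / 1e6
    n_fp = rng.poisson(config.building_density * area_km2)
    footprints = []
    from shapely.geometry import box

    for j in range(n_fp):
        cx, cy = rng.uniform(x0, x1), rng.uniform(y0, y1)
        w, h = rng.uniform(8.0, 20.0, 2)
        kind = "tree" if rng.random() < config.tree_share else "building"
        footprints.append(
            Footprint(
                footprint_id=f"F{j:06d}",
                polygon=box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2),
                kind=kind,
            )
        )
    return residences, footprints


def gen_windows(
    config: SimulationConfig,
    n: int,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Birth dates uniform over the study years; gestation ~ configured
    categorical; conception = birth - 7 * gestational weeks (days)."""
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    y0, y1 = config.study_years
    start = pd.Timestamp(f"{y0}-01-01")
    end = pd.Timestamp(f"{y1}-12-31")
    days = (end - start).days
    birth = start + pd.to_timedelta(rng.integers(0, days + 1, n), unit="D")
    weeks_levels = np.array(sorted(config.gestation_weights))
    p = np.array([config.gestation_weights[w] for w in weeks_levels], dtype=float)
    p = p / p.sum()
    weeks = rng.choice(weeks_levels, size=n, p=p)
    conception = birth - pd.to_timedelta(weeks * 7, unit="D")
    return pd.DataFrame(
        {
            "birth_date": birth,
            "conception_date": conception,
            "birth_year": birth.year,
            "gestational_weeks": weeks,
        }
    )


# ---------------------------------------------------------------------------
# scenario assembly (geometry + wind + exposure, shared across replicates)
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """A fully assembled synthetic study system.

    ``cohort`` holds one row per in-study residence: location, pregnancy
    window, design gestation, and the computed wind-exposure summary — the
    inputs that matching and the outcome generator consume.
    """

    config: SimulationConfig
    roads: list[Road]
    segment_index: SegmentIndex
    residences: pd.DataFrame
    footprints: list[Footprint]
    winds: WindSeries
    cohort: pd.DataFrame


def build_scenario(config: SimulationConfig) -> Scenario:
    """Generate all layers and run the exposure assessment once."""
    rng = np.random.default_rng(config.seed)
    roads = gen_roads(config, np.random.default_rng(rng.integers(2**31)))
    residences, footprints = gen_residences(
        config, roads, np.random.default_rng(rng.integers(2**31))
    )
    windows = gen_windows(
        config, len(residences), np.random.default_rng(rng.integers(2**31))
    )
    cohort = pd.concat([residences, windows], axis=1)
    wind_start = pd.Timestamp(cohort["conception_date"].min()).normalize()
    wind_end = pd.Timestamp(cohort["birth_date"].max()).normalize() + pd.Timedelta(hours=23)
    winds = gen_wind(config, wind_start, wind_end, np.random.default_rng(rng.integers(2**31)))
    high = geo_prep.filter_high_traffic(roads, config.study_years[0])
    index = SegmentIndex(geo_prep.segment_roads(high))
    summaries = wind_exposure.cohort_downwind_summaries(cohort, winds, index)
    cohort = cohort.merge(summaries, on="residence_id", how="inner")
    return Scenario(
        config=config,
        roads=roads,
        segment_index=index,
        residences=residences,
        footprints=footprints,
        winds=winds,
        cohort=cohort,
    )


def compute_shielding(scenario: Scenario) -> pd.DataFrame:
    """Max-road building/tree shielding per cohort residence (optional, slow)."""
    segs = {s.segment_id: s for s in scenario.segment_index.segments}
    rows = []
    for rec in scenario.cohort.itertuples():
        res = geo_prep.Residence(rec.residence_id, np.array([rec.x, rec.y]))
        summary = type("S", (), {"max_segment_id": rec.max_segment_id})
        b, t = shielding.max_road_shielding(summary, res, segs, scenario.footprints)
        rows.append(
            {"residence_id": rec.residence_id, "bldg_shield_max": b, "tree_shield_max": t}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# birth records (outcome stage; re-drawable per replicate)
# ---------------------------------------------------------------------------

def _centered_choice(rng, n, levels, probs, effects):
    """Draw a categorical covariate; return (values, centered effect)."""
    probs = np.asarray(probs, dtype=float)
    probs = probs / probs.sum()
    effects = np.asarray(effects, dtype=float)
    idx = rng.choice(len(levels), size=n, p=probs)
    centered = effects - probs @ effects
    return np.asarray(levels, dtype=object)[idx], centered[idx]


def gen_births(
    config: SimulationConfig,
    cohort: pd.DataFrame,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Birth records for a scenario cohort with the configured true effects.

    The downwind indicator is pct_downwind_max >= cohort median, so the
    exposed (top-quartile) vs control (bottom-quartile) contrast equals the
    configured gram effect exactly.  Covariates are independent of wind side;
    with ``config.confounding`` smoking and an unmeasured disadvantage term
    become functions of road distance.  Gestational age is the design draw
    unless a binary-outcome log-odds effect is configured, in which case the
    preterm/very-preterm indicators are redrawn with the exposure shift.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 7 if seed is None else seed)
    n = len(cohort)
    pct = cohort["pct_downwind_max"].to_numpy(dtype=float)
    x = (pct >= np.median(pct)).astype(int)
    d = cohort["nearest_road_distance"].to_numpy(dtype=float)

    eff = np.zeros(n)
    sex, e = _centered_choice(rng, n, ["F", "M"], [0.49, 0.51], [-60.0, 60.0])
    eff += e
    maternal_age = np.clip(rng.normal(27.0, 6.0, n), 15.0, 45.0)
    eff += 1.0 * (maternal_age - 27.0)
    county, e = _centered_choice(
        rng, n, ["Alpha", "Bravo", "Charlie", "Delta"], [0.4, 0.3, 0.2, 0.1],
        [20.0, -10.0, 0.0, -30.0],
    )
    eff += e
    race, e = _centered_choice(
        rng, n, ["white", "black", "hispanic", "asian", "other"],
        [0.35, 0.12, 0.40, 0.05, 0.08], [30.0, -60.0, -10.0, 20.0, 0.0],
    )
    eff += e
    foreign, e = _centered_choice(rng, n, [False, True], [0.67, 0.33], [0.0, 15.0])
    eff += e
    payment, e = _centered_choice(
        rng, n, ["medicaid", "private", "self_pay", "other"],
        [0.50, 0.30, 0.12, 0.08], [-30.0, 30.0, -10.0, 0.0],
    )
    eff += e
    wic, e = _centered_choice(rng, n, [False, True], [0.65, 0.35], [0.0, -20.0])
    eff += e

    disadvantage = 1.0 - d / 500.0
    if config.confounding:
        logit_p = np.log(0.05 / 0.95) + config.confound_smoking_logodds * (
            disadvantage - disadvantage.mean()
        )
        smoking = rng.random(n) < 1.0 / (1.0 + np.exp(-logit_p))
    else:
        smoking = rng.random(n) < 0.05
    eff += np.where(smoking, -180.0, 0.0) - (-180.0 * 0.05)

    weight_gain = np.clip(rng.normal(30.0, 10.0, n), 0.0, 80.0)
    eff += 2.0 * (weight_gain - 30.0)
    pnc_levels = list(range(0, 10))
    pnc_probs = [0.02, 0.10, 0.25, 0.25, 0.13, 0.09, 0.06, 0.05, 0.03, 0.02]
    pnc_effects = [-60.0, -5.0, 0.0, 0.0, -5.0, -10.0, -15.0, -20.0, -25.0, -30.0]
    prenatal, e = _centered_choice(rng, n, pnc_levels, pnc_probs, pnc_effects)
    eff += e
    income, e = _centered_choice(
        rng, n, ["low", "middle", "high"], [1 / 3, 1 / 3, 1 / 3], [-40.0, 0.0, 40.0]
    )
    eff += e
    education, _ = _centered_choice(
        rng, n,
        ["less_than_hs", "high_school", "bachelors", "graduate"],
        [0.07, 0.50, 0.36, 0.07], [0.0, 0.0, 0.0, 0.0],
    )

    # true downwind effect on term birth weight
    downwind_eff = config.effect_tbw_downwind * x.astype(float)
    if config.effect_decay_length is not None:
        downwind_eff *= np.exp(-d / config.effect_decay_length)
    if config.effect_tbw_modifier is not None:
        col, mapping = config.effect_tbw_modifier
        local = {"education": education, "income_tertile": income, "race_ethnicity": race}[col]
        downwind_eff = x.astype(float) * np.array(
            [mapping.get(v, config.effect_tbw_downwind) for v in local]
        )
        if config.effect_decay_length is not None:
            downwind_eff *= np.exp(-d / config.effect_decay_length)
    if config.confounding:
        eff += config.confound_tbw * (disadvantage - disadvantage.mean())

    weeks = cohort["gestational_weeks"].to_numpy(dtype=int).copy()
    lo_ptb = float(config.effect_logodds.get("ptb", 0.0))
    lo_vptb = float(config.effect_logodds.get("vptb", 0.0))
    if lo_ptb != 0.0 or lo_vptb != 0.0:
        weeks = _redraw_gestation(config, rng, n, x, lo_ptb, lo_vptb)

    weeks_levels = np.array(sorted(config.gestation_weights))
    w_p = np.array([config.gestation_weights[w] for w in weeks_levels], dtype=float)
    term_mask = weeks_levels >= 37
    term_mean_weeks = float(
        (weeks_levels[term_mask] * w_p[term_mask]).sum() / w_p[term_mask].sum()
    )
    week_adj = config.grams_per_week * (weeks - term_mean_weeks)
    birth_weight = (
        config.baseline_tbw_mean
        + week_adj
        + eff
        + downwind_eff
        + rng.normal(0.0, config.baseline_tbw_sd, n)
    )
    birth_weight = np.maximum(birth_weight, 150.0)

    records = pd.DataFrame(
        {
            "birth_record_id": cohort["birth_record_id"].to_numpy(),
            "residence_id": cohort["residence_id"].to_numpy(),
            "birth_weight": birth_weight,
            "gestational_weeks": weeks,
            "sex": sex,
            "maternal_age": maternal_age,
            "birth_month": pd.to_datetime(cohort["birth_date"]).dt.month.to_numpy(),
            "birth_year": cohort["birth_year"].to_numpy(),
            "county": county,
            "race_ethnicity": race,
            "foreign_born": foreign,
            "payment": payment,
            "wic": wic,
            "smoking": smoking,
            "weight_gain": weight_gain,
            "prenatal_care_month": prenatal,
            "income_tertile": income,
            "education": education,
            "nearest_road_distance": d,
            "pct_downwind_max": pct,
            "mean_pct_downwind": cohort["mean_pct_downwind"].to_numpy(),
            "downwind_true": x,
        }
    )
    return records


def _redraw_gestation(config, rng, n, x, lo_ptb, lo_vptb):
    """Resample gestational weeks with exposure-shifted preterm odds."""
    weeks_levels = np.array(sorted(config.gestation_weights))
    p = np.array([config.gestation_weights[w] for w in weeks_levels], dtype=float)
    p = p / p.sum()
    p_ptb = p[weeks_levels < 37].sum()
    p_vptb_given_ptb = p[weeks_levels < 32].sum() / p_ptb
    logit = lambda q: np.log(q / (1 - q))
    expit = lambda z: 1.0 / (1.0 + np.exp(-z))
    ptb = rng.random(n) < expit(logit(p_ptb) + lo_ptb * x)
    vptb = ptb & (rng.random(n) < expit(logit(p_vptb_given_ptb) + lo_vptb * x))
    weeks = np.empty(n, dtype=int)
    for mask, sel in (
        (~ptb, weeks_levels >= 37),
        (ptb & ~vptb, (weeks_levels >= 32) & (weeks_levels < 37)),
        (vptb, weeks_levels < 32),
    ):
        k = int(mask.sum())
        if k:
            sub_p = p[sel] / p[sel].sum()
            weeks[mask] = rng.choice(weeks_levels[sel], size=k, p=sub_p)
    return weeks


def replicate_seeds(master_seed: int, n: int) -> list[int]:
    """Independent child seeds (< 2^31) for outcome-stage replicates."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n)]


def simulate(config: SimulationConfig, outdir: str | Path) -> Scenario:
    """Generate a full scenario and write all layers in consumable formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenario = build_scenario(config)
    geo_prep.roads_to_geojson(scenario.roads, outdir / "roads.geojson")
    shielding.footprints_to_geojson(scenario.footprints, outdir / "buildings.geojson")
    scenario.winds.to_csv(outdir / "wind.csv")
    records = gen_births(config, scenario.cohort)
    cohort_cols = [
        "residence_id", "birth_record_id", "x", "y",
        "conception_date", "birth_date",
    ]
    births = scenario.cohort[cohort_cols].merge(
        records.drop(columns=["residence_id"]), on="birth_record_id"
    )
    births.to_csv(outdir / "births.csv", index=False)
    scenario.cohort.to_csv(outdir / "exposure_summaries.csv", index=False)
    config.to_yaml(outdir / "config.yaml")
    return scenario
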