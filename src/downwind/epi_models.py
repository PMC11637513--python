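"""Matched-individual regression models for birth outcomes.

Individuals from the matched exposed (downwind) / control (upwind) sets are
analysed with plain linear regression (term birth weight, grams) and logistic
regression (low TBW, PTB, very PTB, odds ratios), exposure coded as a
downwind indicator with upwind as the reference.  Standard errors are
cluster-robust by matched set by default (``plain_se=True`` mimics an
uncorrected fit).  Stratified variants (distance to the nearest road,
sociodemographic subgroups, rolling birth-year windows), a continuous
percent-downwind exposure, and shielding-adjusted fits cover the sensitivity
analyses.  Non-convergent or degenerate fits are reported with
``converged=False`` rather than raised.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger("downwind.epi")


@dataclass(frozen=True)
class OutcomeDefinition:
    """A birth outcome: its type, cohort restriction, and event rule."""

    name: str
    kind: str  # "continuous" | "binary"
    weeks_range: tuple[int, int]
    gestation_covariate: bool = False


#: The four study outcomes.  TBW and low TBW are restricted to term births
#: (37-42 completed weeks); PTB is 22 to <37 weeks, very PTB 22 to <32 weeks,
#: both over the 22-42-week cohort.
OUTCOMES: dict[str, OutcomeDefinition] = {
    "tbw": OutcomeDefinition("tbw", "continuous", (37, 42), gestation_covariate=True),
    "low_tbw": OutcomeDefinition("low_tbw", "binary", (37, 42)),
    "ptb": OutcomeDefinition("ptb", "binary", (22, 42)),
    "vptb": OutcomeDefinition("vptb", "binary", (22, 42)),
}

BASE_COVARIATES: tuple[str, ...] = (
    "C(sex)",
    "maternal_age",
    "C(birth_month)",
    "C(birth_year)",
    "nearest_road_distance",
    "C(county)",
)
FULL_EXTRA_COVARIATES: tuple[str, ...] = (
    "C(race_ethnicity)",
    "C(foreign_born)",
    "C(payment)",
    "C(wic)",
    "C(smoking)",
    "weight_gain",
    "C(prenatal_care_month)",
    "C(income_tertile)",
)
DISTANCE_BINS: tuple[tuple[float, float], ...] = (
    (0, 50),
    (51, 100),
    (101, 300),
    (301, 400),
    (401, 500),
)


@dataclass
class EffectEstimate:
    """One fitted downwind effect: grams (linear) or odds ratio (logistic)."""

    outcome: str
    model: str  # "base" | "full"
    scale: str  # "grams" | "odds-ratio"
    point: float
    ci_low: float
    ci_high: float
    n_pairs: int
    n_events: int | None
    stratum: str | None = None
    converged: bool = True

    def as_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "model": self.model,
            "stratum": self.stratum,
            "scale": self.scale,
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_pairs": self.n_pairs,
            "n_events": self.n_events,
            "converged": self.converged,
        }


def _unconverged(outcome: str, model: str, scale: str, stratum: str | None) -> EffectEstimate:
    return EffectEstimate(
        outcome=outcome,
        model=model,
        scale=scale,
        point=float("nan"),
        ci_low=float("nan"),
        ci_high=float("nan"),
        n_pairs=0,
        n_events=None,
        stratum=stratum,
        converged=False,
    )


def outcome_values(records: pd.DataFrame, outcome: OutcomeDefinition) -> pd.Series:
    """The modelled response for each record."""
    w = records["gestational_weeks"]
    if outcome.name == "tbw":
        return records["birth_weight"].astype(float)
    if outcome.name == "low_tbw":
        return (records["birth_weight"] < 2500).astype(int)
    if outcome.name == "ptb":
        return (w < 37).astype(int)
    if outcome.name == "vptb":
        return (w < 32).astype(int)
    raise KeyError(outcome.name)


def build_frame(
    matches: pd.DataFrame,
    records: pd.DataFrame,
    outcome: OutcomeDefinition,
) -> pd.DataFrame:
    """One row per matched individual with response, exposure, and cluster id.

    ``records`` is indexed by residence_id.  Individuals outside the outcome's
    gestational-age range are dropped; a matched set survives only while its
    exposed member and at least one control remain.
    """
    lo, hi = outcome.weeks_range
    ok = records[(records["gestational_weeks"] >= lo) & (records["gestational_weeks"] <= hi)]
    m = matches[matches["exposed_id"].isin(ok.index) & matches["control_id"].isin(ok.index)]
    if m.empty:
        return pd.DataFrame()
    exposed = ok.loc[m["exposed_id"].unique()].copy()
    exposed["downwind"] = 1
    exposed["set_id"] = exposed.index
    controls = ok.loc[m["control_id"]].copy()
    controls["downwind"] = 0
    controls["set_id"] = m["exposed_id"].to_numpy()
    df = pd.concat([exposed, controls])
    df["y"] = outcome_values(df, outcome)
    df["n_pairs_"] = len(m)
    return df.reset_index(names="residence_id")


def _active_terms(df: pd.DataFrame, terms: Iterable[str]) -> list[str]:
    """Drop constant covariates; set each categorical's reference level to its
    most frequent category."""
    out = []
    for t in terms:
        categorical = t.startswith("C(")
        col = t[2:-1] if categorical else t
        if col not in df.columns:
            logger.warning("covariate %s missing from records; dropped", col)
            continue
        if df[col].nunique(dropna=False) <= 1:
            logger.info("covariate %s is constant in this cohort; dropped", col)
            continue
        if categorical:
            ref = df[col].mode(dropna=True).iloc[0]
            if hasattr(ref, "item"):
                ref = ref.item()
            out.append(f"C({col}, Treatment({ref!r}))")
        else:
            out.append(t)
    return out


def _covariate_terms(
    df: pd.DataFrame,
    outcome: OutcomeDefinition,
    covariate_set: str,
    drop: Sequence[str] = (),
    extra: Sequence[str] = (),
) -> list[str]:
    terms = list(BASE_COVARIATES)
    if outcome.gestation_covariate:
        terms.append("C(gestational_weeks)")
    if covariate_set == "full":
        terms += list(FULL_EXTRA_COVARIATES)
    elif covariate_set != "base":
        raise ValueError("covariate_set must be 'base' or 'full'")
    terms = [t for t in terms if (t[2:-1] if t.startswith("C(") else t) not in drop]
    terms += list(extra)
    return _active_terms(df, terms)


def _fit(
    df: pd.DataFrame,
    outcome: OutcomeDefinition,
    covariate_set: str,
    exposure_term: str,
    plain_se: bool,
    stratum: str | None,
    drop: Sequence[str] = (),
    extra: Sequence[str] = (),
    rescale: float = 1.0,
) -> EffectEstimate:
    scale = "grams" if outcome.kind == "continuous" else "odds-ratio"
    if df.empty or df["downwind"].nunique() < 2:
        return _unconverged(outcome.name, covariate_set, scale, stratum)
    terms = _covariate_terms(df, outcome, covariate_set, drop=drop, extra=extra)
    formula = "y ~ " + " + ".join([exposure_term] + terms)
    fit_kw: dict = {}
    if not plain_se:
        fit_kw = {"cov_type": "cluster", "cov_kwds": {"groups": df["set_id"]}}
    n_pairs = int(df["n_pairs_"].iloc[0])
    n_events = int(df["y"].sum()) if outcome.kind == "binary" else None

    def fail() -> EffectEstimate:
        est = _unconverged(outcome.name, covariate_set, scale, stratum)
        est.n_pairs, est.n_events = n_pairs, n_events
        return est

    param = exposure_term.split("(")[0].strip()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if outcome.kind == "continuous":
                res = smf.ols(formula, df).fit(**fit_kw)
                converged = True
            else:
                if df["y"].nunique() < 2:
                    return fail()
                res = smf.logit(formula, df).fit(disp=0, maxiter=200, **fit_kw)
                converged = bool(res.mle_retvals.get("converged", True))
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError, KeyError) as exc:
        logger.warning("fit failed (%s): %s", outcome.name, exc)
        return fail()
    if param not in res.params.index:
        # patsy renames the plain exposure column only if it was transformed
        cand = [p for p in res.params.index if p.startswith(param)]
        if not cand:
            return fail()
        param = cand[0]
    point = float(res.params[param]) * rescale
    ci = res.conf_int().loc[param] * rescale
    lo_ci, hi_ci = float(ci[0]), float(ci[1])
    if not np.isfinite([point, lo_ci, hi_ci]).all():
        return fail()
    if outcome.kind == "binary":
        point, lo_ci, hi_ci = float(np.exp(point)), float(np.exp(lo_ci)), float(np.exp(hi_ci))
    return EffectEstimate(
        outcome=outcome.name,
        model=covariate_set,
        scale=scale,
        point=point,
        ci_low=lo_ci,
        ci_high=hi_ci,
        n_pairs=n_pairs,
        n_events=n_events,
        stratum=stratum,
        converged=converged,
    )


def fit_model(
    matches: pd.DataFrame,
    records: pd.DataFrame,
    outcome: OutcomeDefinition | str,
    covariate_set: str = "base",
    plain_se: bool = False,
    stratum: str | None = None,
) -> EffectEstimate:
    """Downwind-vs-upwind effect on one outcome (grams or odds ratio)."""
    outcome = OUTCOMES[outcome] if isinstance(outcome, str) else outcome
    df = build_frame(matches, records, outcome)
    return _fit(df, outcome, covariate_set, "downwind", plain_se, stratum)


def fit_continuous(
    matches: pd.DataFrame,
    records: pd.DataFrame,
    outcome: OutcomeDefinition | str,
    covariate_set: str = "base",
    per: float = 10.0,
    plain_se: bool = False,
) -> EffectEstimate:
    """Continuous-exposure sensitivity model: effect per ``per``-% downwind."""
    outcome = OUTCOMES[outcome] if isinstance(outcome, str) else outcome
    df = build_frame(matches, records, outcome)
    if df.empty or df["pct_downwind_max"].nunique() <= 1:
        raise ValueError("percent-downwind exposure is constant; cannot fit")
    df["pct_exposure"] = df["pct_downwind_max"] / per
    return _fit(df, outcome, covariate_set, "pct_exposure", plain_se, "continuous")


def fit_with_shielding(
    matches: pd.DataFrame,
    records: pd.DataFrame,
    outcome: OutcomeDefinition | str,
    covariate_set: str = "base",
    plain_se: bool = False,
) -> EffectEstimate:
    """Adds max-road building/tree shielding percentages as covariates."""
    outcome = OUTCOMES[outcome] if isinstance(outcome, str) else outcome
    df = build_frame(matches, records, outcome)
    return _fit(
        df,
        outcome,
        covariate_set,
        "downwind",
        plain_se,
        "shielding-adjusted",
        extra=["bldg_shield_max", "tree_shield_max"],
    )


def _distance_label(lo: float, hi: float) -> str:
    return f"{int(lo)}-{int(hi)}"


def fit_distance_strata(
    matches: pd.DataFrame,
    records: pd.DataFrame,
    outcome: OutcomeDefinition | str,
    covariate_set: str = "base",
    bins: Sequence[tuple[float, float]] = DISTANCE_BINS,
    plain_se: bool = False,
) -> list[EffectEstimate]:
    """One estimate per nearest-road-distance bin (pair assigned by the
    exposed member's own nearest-road distance)."""
    outcome = OUTCOMES[outcome] if isinstance(outcome, str) else outcome
    dist = records["nearest_road_distance"]
    out = []
    edges = [b[1] for b in bins]
    exposed_bin = np.digitize(dist.loc[matches["exposed_id"]].to_numpy(), edges, right=True)
    for i, (lo, hi) in enumerate(bins):
        label = _distance_label(lo, hi)
        m = matches[exposed_bin == i]
        if m.empty:
            out.append(
                _unconverged(
                    outcome.name,
                    covariate_set,
                    "grams" if outcome.kind == "continuous" else "odds-ratio",
                    label,
                )
            )
            continue
        df = build_frame(m, records, outcome)
        out.append(_fit(df, outcome, covariate_set, "downwind", plain_se, label))
    return out


def fit_covariate_strata(
    matches: pd.DataFrame,
    records: pd.DataFrame,
    outcome: OutcomeDefinition | str,
    covariate_set: str = "full",
    stratum_var: str = "race_ethnicity",
    plain_se: bool = False,
) -> list[EffectEstimate]:
    """One estimate per level of a sociodemographic stratifier.

    Individuals are subset by their own stratum level; matched sets keep
    surviving members (exposed plus at least one control required).  The
    stratifier is dropped from the covariate list within its own strata.
    """
    outcome = OUTCOMES[outcome] if isinstance(outcome, str) else outcome
    out = []
    for level in sorted(records[stratum_var].dropna().unique(), key=str):
        sub = records[records[stratum_var] == level]
        m = matches[
            matches["exposed_id"].isin(sub.index) & matches["control_id"].isin(sub.index)
        ]
        df = build_frame(m, sub, outcome)
        out.append(
            _fit(
                df,
                outcome,
                covariate_set,
                "downwind",
                plain_se,
                str(level),
                drop=[stratum_var],
            )
        )
    return out


def rolling_window_fits(
    matches: pd.DataFrame,
    records: pd.DataFrame,
    outcome: OutcomeDefinition | str,
    covariate_set: str = "base",
    window: int = 3,
    plain_se: bool = False,
) -> list[EffectEstimate]:
    """One estimate per contiguous ``window``-year birth-year span (stride 1);
    a pair enters a window by the exposed member's birth year."""
    outcome = OUTCOMES[outcome] if isinstance(outcome, str) else outcome
    years = records["birth_year"].loc[matches["exposed_id"]].to_numpy(dtype=int)
    y0, y1 = int(years.min()), int(years.max())
    starts = range(y0, max(y1 - window + 2, y0 + 1))
    out = []
    for s in starts:
        label = f"{s}-{s + window - 1}"
        m = matches[(years >= s) & (years <= s + window - 1)]
        df = build_frame(m, records, outcome)
        out.append(_fit(df, outcome, covariate_set, "downwind", plain_se, label))
    return out


def estimates_to_frame(estimates: Iterable[EffectEstimate]) -> pd.DataFrame:
    """Tabular export mirroring the published results-table columns."""
    return pd.DataFrame([e.as_dict() for e in estimates])
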