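# Methods

This note records the scientific and numerical choices behind `downwind`:
what the pipeline computes, what the synthetic study system does and does
not emulate, and where the design was genuinely open.

## Exposure model

**Coordinates.** All geometry lives in a projected planar coordinate system
in meters.  Real road networks and footprints must be reprojected before
use; the synthetic generator emits planar meters directly.  Layers may carry
a CRS label and proximity queries refuse to mix differing labels.

**High-traffic roads.** A road is high-traffic in a year when its AADT is
≥ 25,000 vehicles/day (inclusive).  When a year's AADT is missing the
nearest prior year is carried forward and logged; with no prior year the
road is an error, never silently dropped.  Classification uses the year of
birth.  High-traffic roads are segmented into 10-m pieces by arc length; the
final sub-10-m remainder is kept as its own segment because dropping it
would delete road ends next to residences.  Each segment is represented by
its chord; its `length` is the arc length between cut points, so segment
lengths sum exactly to the polyline length.

**Wind from-direction.** ERA5-style u/v components give the direction air
moves toward; the exposure instrument is the reverse (meteorological
from-direction), `(atan2(u, v) + 180°) mod 360`.  Calm hours (u = v = 0)
have no direction: they are excluded from the radial bins but still count
toward pregnancy hours.  Wind is sampled from the nearest grid cell, with no
spatial interpolation — the instrument is regional wind, not micro-scale
flow.

**Radial distribution.** The pregnancy window runs from 00:00 on the
conception day through 23:00 on the birth day, inclusive (m = 24 × inclusive
days).  Each valid hour's from-direction is rounded to the nearest integer
degree j\* and the 31 bins {j\*−15 … j\*+15} (mod 360) are incremented — an
inclusive ±15° window, chosen so one observation always marks exactly 31 of
the 360 one-degree radial segments.  Consequently Σ bins = 31 × valid hours,
an invariant the tests enforce unconditionally.  A configurable completeness
threshold (default: ≥ 95% of window hours present in the wind series) gates
the computation; missing hours behave like calm ones.

**Downwind hours per segment.** A segment is assigned to the single integer
bearing bin of the residence→midpoint direction; its downwind hours d_li are
the radial count at that bin.  For integer-degree winds this equals a
per-hour angular test |bearing − from-direction| ≤ 15° exactly (verified
against a brute-force oracle).  At ranges under ~50 m a 10-m segment spans
more than 1°, so the midpoint assignment is a quantization — acceptable
because adjacent segments of the same road fill the neighboring bins.

**Summaries.** Per residence: mean downwind hours over all n_i segments
within 500 m (zeros included), the max road (argmax segment; ties broken by
smaller residence–midpoint distance, then segment id for determinism), and
the corresponding percent-of-pregnancy quantities.  Segment membership in
the 500-m set uses the segment midpoint, consistent with the bearing join;
the nearest-road covariate uses true point-to-segment distance because it is
a regression covariate, not a radial-join input.

## Shielding

The "between" region for a (residence, segment) pair is the triangle on the
segment endpoints and the residence — the simplest region consistent with
the idea of obstacles sitting between source and receptor; it degrades
gracefully (zero area, shielding 0) when the three points are collinear.
The shielding fraction is the percent of that triangle covered by the union
of same-kind footprints (union semantics: stacked footprints never double
count).  Shielding is computed for the max road only by default and enters
the models purely as an adjustment covariate; it is independent of wind
direction and carries no 3-D information.

## Matching

Exposure groups are quartiles of max-road downwind hours over the full
within-500-m cohort (linear-interpolation percentiles, inclusive at both
cut points; constant inputs are an error).  The match score between an
exposed residence e and control c is

    locality  = |dist(e, max seg of e) − dist(c, same seg)|      (midpoint distances)
    near-road = |nearest-road dist(e) − nearest-road dist(c)|    (point-to-segment)
    score     = locality + near-road + 10·|birth year e − birth year c|

with candidates rejected outright beyond ±4 birth years and included only
when locality < 100 m AND near-road < 100 m, both strict (15/25/50-m
thresholds supported for sensitivity analyses).  Assignment is greedy over
all includable candidates by ascending score (ties: smaller locality, then
stable input order), each exposed capped at 4 controls.  A control serves
one exposed residence only; `allow_control_reuse=True` relaxes this, since
the variance interpretation differs and the original design is ambiguous on
reuse.  The vectorised cohort matcher prunes candidates with a KD-tree
around each exposed residence's max segment (any control farther than
dist + threshold necessarily fails locality) and is tested to agree exactly
with the object-level greedy on exhaustive candidate sets.

For term-birth-weight outcomes the cohort is restricted to 37–42 completed
weeks *before* group assignment and matching; preterm outcomes match on the
unrestricted cohort.

## Regression models

Analyses run at the individual level over matched-set members, exposure
coded downwind = 1 / upwind = 0.  The base covariate set is infant sex,
maternal age (linear), birth month and year (categorical), nearest-road
distance (linear), and county fixed effects; the TBW model adds gestational
week categories (one level per completed week).  The full set adds
race/ethnicity, foreign-born, delivery payment source, WIC participation,
smoking, weight gain (linear), first prenatal-care month, and neighborhood
income tertile.  Categorical reference levels are the most frequent
category; covariates constant within a fitting cohort are dropped with a
log note (which also makes the all-zero-shielding fit identical to the
unadjusted one).

Standard errors are cluster-robust by matched set by default because
controls within a set share their exposed member; `plain_se=True` mimics an
uncorrected fit.  Under the default synthetic conditions the clustered SEs
are well calibrated (type-I error ≈ 5% over 200 null replicates).  Logistic
fits that hit iteration limits, separation, or degenerate outcomes are
returned with `converged=False` (with their cohort sizes and event tallies
intact) rather than raised, so stratified tables can contain
"did not converge" cells.

Stratified variants: distance bins 0–50 / 51–100 / 101–300 / 301–400 /
401–500 m, pairs assigned by the exposed member's own nearest-road distance
(the members' distances differ by < 100 m by construction, so the choice is
minor); sociodemographic strata subset individuals by their own level and
keep sets that retain the exposed member plus at least one control, with the
stratifier dropped from its own strata; the continuous sensitivity model
replaces the indicator with percent-downwind-of-max-road per 10% (linear
rescaling); rolling fits cover every contiguous 3-year birth-year window
with stride 1, pairs entering by the exposed member's birth year.

## Synthetic study system

The generator emulates the analysis inputs with one master seed controlling
every layer (byte-identical reruns):

* **Roads** — parallel east-west polylines, half gently curved (low-amplitude
  sine), with per-year AADT drawn so a configurable share (default 70%)
  exceeds 25,000; yearly jitter never flips a road across the threshold.
* **Wind** — hourly from-directions ~ von Mises(prevailing direction, κ),
  speeds ~ Gamma(shape 2, scale 2.5; mean 5 m/s), 1% calm hours.  κ defaults
  to 1.5, a clearly prevailing but realistic regime.
* **Residences** — on both sides of high-traffic roads (≈50/50), offset
  10–500 m.  Offsets mix a near-road-skewed Beta(1, 8) component (75%) with
  a uniform tail (25%), emulating housing density clustering along arterial
  corridors.  This skew matters: near-road residences see road segments
  across a ~180° bearing arc, so their max-road hours can never be
  bottom-quartile unless the quartile boundary sits near the road — with
  uniform offsets the control group contains no near-road homes at all and
  the 0–50/51–100 m strata of the distance-stratified analysis would be
  structurally empty.  Even with the skew, near-road matches remain the
  scarcest, which mirrors the real design's behavior.
* **Pregnancies** — birth dates uniform over the study years (default
  2007–2016); gestational weeks from a 22–42-week categorical (≈9% preterm,
  ≈1.4% very preterm); conception = birth − 7 × weeks days.
* **Outcomes** — the downwind indicator is pct-downwind-of-max-road ≥ the
  cohort median, so the exposed (top-quartile) vs control (bottom-quartile)
  regression contrast equals the configured effect exactly.  Term birth
  weight is Normal(3300 + 140 g/week (centered within term) + centered
  covariate effects + injected effect, sd 450).  The injected effect can be
  homogeneous (default −30 g), exponentially decaying with nearest-road
  distance (`effect_decay_length`), or modified per stratum of a chosen
  covariate.  Binary-outcome log-odds effects re-draw the preterm/very-
  preterm indicators with the exposure shift and resample weeks within
  category.  All covariates are drawn independent of wind side — instrument
  validity by construction — and every covariate effect is centered so the
  population mean stays at the configured baseline.
* **Confounding switch** — adds an unmeasured disadvantage term
  (−80 g per unit of 1 − d/500) and a smoking gradient toward the road.
  This biases naive near/far-road comparisons while leaving the matched
  downwind/upwind contrast unaffected, which is the design's central claim
  and is verified in simulation.

What the generator does **not** emulate: real Texas demographics, seasonal
or multimodal wind climatology, street-canyon or turbulence effects,
residential mobility during pregnancy, geocoding error, or correlated
pregnancy outcomes within families.  Passing tests therefore demonstrate
that the *method* recovers known effects under its own assumptions, not
that any particular real-world estimate is correct.

### Replication design

Geography, wind, pregnancy windows (including gestation), exposure, and
matches are built once per scenario seed; only covariates and outcome noise
are redrawn per replicate, with child seeds spawned from a fixed master.
This is conditional-on-design replication of the estimator's sampling
distribution: it isolates outcome-stage variability (the dominant source at
these sample sizes) and keeps 50-replicate suites fast.  Because gestation
is part of the fixed design when no binary effect is configured, the
term-restricted matched sets are identical across replicates.

### Problem sizes

The recovery/calibration/decay/confounding suites and the acceptance script
use one 20-km high-traffic road with 20,000 residences, which yields ≈4,600
matched term pairs (the bottom-quartile control pool is nearly exhausted, so
pair count ≈ cohort/4) — large enough that a −30 g effect is comfortably
inside estimator resolution (per-replicate SE ≈ 13 g).  The distance-decay
suite injects −60 g × exp(−d/150 m): the decay *shape* is the scientific
condition, and the larger amplitude gives the qualitative monotone gradient
adequate Monte-Carlo power at 20 replicates; a separate 100-replicate check
at −30 g confirms per-bin estimates are unbiased.  The default
`SimulationConfig` (2,000 residences, 3 roads) runs the full pipeline in a
few seconds and is meant for interactive use.

## Numerical notes and edge cases

* Quantile definition: NumPy's linear-interpolation quantiles, inclusive at
  both boundaries; degenerate (constant) inputs raise.
* Max-road ties: smaller residence–midpoint distance, then segment id.
* Greedy-match ties: smaller locality score, then stable candidate order —
  identical inputs yield identical matches; shuffling input order can only
  permute exact ties.
* Bearings/bins: `round` to nearest integer degree, modulo 360; a residence
  coincident with a segment midpoint has no bearing and raises.
* Segmentation tolerance: 1e-6 m on arc-length conservation; a trailing
  remainder below tolerance is merged into the last segment.
* Degenerate covariates (single level in a fitting cohort) are dropped, and
  saturated or separated fits come back flagged rather than raising.

## Known limitations

* The matcher is greedy, not an optimal assignment; the original design
  language ("priority to the lowest match score") reads as greedy, and an
  exhaustive-enumeration oracle pins down the exact semantics in tests.
* Whether a control may serve several exposed residences is ambiguous in
  the source design; reuse is off by default and switchable.
* Shielding uses 2-D footprints and a triangular between-region; no heights,
  no wind-direction dependence.
* The per-segment radial join uses midpoints; sub-degree geometry within
  50 m of a segment is quantized.
* When a binary-outcome effect is configured, gestation is redrawn at the
  outcome stage while conception dates (and hence exposure windows) keep the
  design draw — exposure is not recomputed for the shifted gestation.  With
  the default null binary effects the two are identical.
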