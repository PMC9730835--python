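# Methods

This note documents the scoring model, its tunable parameters, the
synthetic-data generator, and the numerical and design choices behind
`soilscore`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scoring model

### Indicator evaluation

A *battery* is a configured list of soil functions, each mapped to one
of five categories (chemical, physical, biological, environmental,
management) and to one evaluation curve per soil-type × land-use
stratum (with `*` wildcards; resolution order: exact, soil-only,
land-use-only, global). Four curve shapes are supported:

* **two-anchor increasing/decreasing** — piecewise linear through
  `(x_zero, 0)`, `(x_half, 0.5)`, `(x_opt, 1)`, clipped outside. The two
  informative anchors are agronomic: 0.5 marks the level below which
  additional fertilization is advised, 1 the optimum beyond which
  yield no longer responds. When `x_zero` is omitted it defaults to
  `2·x_half − x_opt` (clipped at 0 for increasing curves), extending
  the upper segment's slope symmetrically. Piecewise-linear was chosen
  over logistic/parabolic forms because it is exact at both anchors,
  trivially invertible, and adds no shape parameters the configuration
  cannot justify.
* **optimum window** — a trapezoid for functions with a two-sided
  optimum (soil acidity): 0 outside `[low0, high0]`, 1 on
  `[low1, high1]`, linear shoulders.
* **categorical lookup** — for class-valued drivers (drought and
  wetness stress from the ordinal groundwater class), with an optional
  default for unknown keys (strict mode raises instead).

The management category is a single indicator carrying an externally
supplied 0–1 management sub-score; it is passed through an identity
two-anchor curve (`x_zero=0, x_half=0.5, x_opt=1`) and flagged
`source=config`, so no fifth curve kind is needed.

Missing required properties yield a *missing* indicator (never 0);
aggregation later excludes missing values and renormalizes weights,
which is equivalent to aggregating only the present values. A battery
must contain at least two chemical, two physical and two biological
functions; this is enforced at load time.

The shipped battery (`src/soilscore/data/battery.yaml`) has 22
functions (9 chemical, 8 physical, 2 biological, 2 environmental,
1 management). Its curve parameters are **illustrative**: plausible
for Dutch-style mineral and peat topsoils, chosen once so that typical
simulated profiles land in the sufficient-to-good range, but not an
authoritative fertilizer-recommendation calibration. Everything is
overridable via a user battery file.

### Aggregation

Three steps, each with one correction factor, all configurable via
`AggregationConfig`:

| step | scope | weight | default | rationale |
|---|---|---|---|---|
| 1 | indicators → category-year score | `w = 1/(I + c)` | `c = 0.2` | law of the minimum: the most limiting function dominates; smooth, strictly decreasing, idempotent for equal inputs |
| 2 | category-years → category sub-score | recency | 1.0 if age < 5, else 0.5 | recent years describe the current rotation better |
| 3 | sub-scores → final score | `W = log2(n + 1)` | — | categories backed by more measured functions are better supported; diminishing returns |

`n_k` in step 3 counts the distinct functions contributing at least one
non-missing value across the field's years. The management category can
be excluded (`include_management=false`) when management data are
nominal rather than observed. Provable properties (all tested):
idempotence (constant v in ⇒ v out, to < 1e-12), monotonicity in every
indicator, bounds (each aggregate lies within the min/max of its
inputs, enforced exactly by a final clip against floating-point dust),
and the limiting-factor inequality (step 1 ≤ arithmetic mean, equality
iff constant — weights are anti-monotone in values, so the
covariance-form of Chebyshev's sum inequality applies).

Classification of any 0–1 score: good (> 0.75), sufficient (0.5–0.75,
both boundaries inclusive), poor (< 0.5).

### VSA substitution and advice

The nine-item visual assessment maps poor/moderate/good to
{0, 0.5, 1}, aligning the three-level field scale with the indicator
midpoint (configurable). Its compaction and structure items replace
the subsoil-compaction and aggregate-stability indicators; the other
seven items currently inform only the overall VSA mean. Substitution
is idempotent and touches exactly those two functions.

Practice benefit is `Σ_f e(p, f)·(1 − I_f)` over a category's
functions — linear in the remaining deficiency, mirroring the
distance-to-target logic; the formula is this package's design (the
underlying intent is "improve poorly scored functions most
effectively"). Ties break lexicographically on the practice id, making
recommendations deterministic. The shipped effectiveness matrix is an
illustrative expert-style stand-in; codes M4/M5/M9 are conventional
assignments (tagetes/deep-rooting crops, legumes, straw residues).

## Synthetic data

The generator emulates multi-year Dutch-style field records:

* **Soil types** sand/clay/loess/peat mixed 0.45/0.35/0.08/0.12 by
  default; per-type property distributions are truncated normals with
  illustrative means/sds (e.g. sand: OM 4.5 ± 1.5 %, pH 5.4 ± 0.4,
  bulk density 1.45 ± 0.10 g/cm³; peat: OM 22 ± 6 %, total N
  9000 ± 2500 mg/kg). Draws use exact inverse-CDF truncated-normal
  sampling.
* **Latent field quality** `q ~ N(0, 0.5)` shifts quality-linked
  properties coherently (loadings: OM +1, PMN +1, bulk density −1,
  P/K +0.3), so indicators correlate across a survey the way good and
  poor fields do; this also gives the PCA diagnostics structure to
  find.
* **Rotation**: a persistent Markov chain (stay-probability 0.85,
  otherwise redraw from the per-soil-type land-use mix), whose
  stationary distribution is the mix itself. Texture and groundwater
  class are constant per field; other properties get small independent
  year-to-year jitter (sd = 5 % of the property sd).
* **VSA**: each item's rating latent is driven by the properties an
  observer actually sees — bulk density for compaction/rooting, OM and
  PMN for structure and biota, groundwater depth for wetness signs —
  plus the quality latent and observer noise (sd 0.08 on the 0–1
  scale), then discretized at 1/3 and 2/3. An earlier draft drew
  ratings almost independently of the simulated soil; that made VSA
  pure noise, which is not what a spade test is.
* **Pairs** (good/poor): members share soil type, hydrology and
  rotation; the poor member's deficiency-linked properties (OM, PMN
  down; bulk density up) are moved `pair_offset` of the way toward
  their deficient truncation bound, and its VSA latent drops by
  `2·pair_offset`. At `pair_offset = 0` the members differ only by
  independent year jitter and observation noise (exchangeable).

What the generator does **not** emulate: spatial structure
(kriging-style autocorrelation), measurement-method biases between
laboratories, real national threshold calibrations, or yield data.
Passing tests therefore demonstrate internal consistency, sensitivity
behaviour and rank-recovery power of the index under controlled
conditions — not agreement with any national survey.

## Problem sizes and numerics

The test suite and acceptance script use desk-scale sizes chosen to
make sampling oracles sharp while keeping runs quick: 400-field
surveys, 11 field pairs (recovery rates averaged over 50 seeds for the
offset-monotonicity check), 10,000-row tables for distributional and
ordering checks, n = 10,000 for the duplicated-column PCA oracle
(analytic first-axis fraction 2/p ± 0.01).

Numerical choices: all aggregation in double precision; weighted means
clipped to the exact [min, max] of their inputs; PCA eigenvalues from
`numpy.linalg.eigh` of the correlation matrix, negative round-off
eigenvalues clipped to 0, fractions normalized by the eigenvalue sum;
Spearman correlations with pairwise deletion (≥ 3 complete pairs,
constant columns reported missing with a warning); PCA on complete
cases, requiring more rows than columns. CSV output is
locale-independent (UTF-8, `.` decimal, fixed column order, floats at
6 significant digits) so repeated runs are byte-identical.

The aggregation-method comparison (`compare_aggregations`) operates on
a flat indicator row: *nonlinear* is the distance-to-target weighted
mean over all of a row's indicators, *linear* the arithmetic mean,
*minimum* the strict limiting-factor reading. On a flat row
`minimum ≤ nonlinear ≤ linear` holds for every input; applying the
equal-weight variant to the full three-step hierarchy instead would
break that guarantee, because step-3 count weights can up-weight a
large high-scoring category past the flat mean.

## Known limitations

* The shipped battery and effectiveness matrix are illustrative; all
  reported scores are meaningful relative to that configuration only.
* Curves are univariate (first required property drives the curve);
  functions needing multivariate pedotransfer logic must be
  pre-computed into a property column.
* Seven of nine VSA items do not yet feed the score (only compaction
  and structure substitute indicators).
* Step 2 aggregates category scores (not indicators) across years; if
  land use changes mid-rotation the yearly curves change stratum, which
  is intended but means a category's year series can mix calibrations.
* Error propagation is single-property and deterministic; no Monte
  Carlo over joint measurement-error distributions.
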