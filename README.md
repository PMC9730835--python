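# soilscore

Hierarchical, config-driven soil-health assessment for agricultural
fields. `soilscore` converts routinely measured topsoil properties and
field context into unitless 0–1 *soil-function indicators*, aggregates
them through three weighted steps into category sub-scores and a final
soil-health score, substitutes in-field visual soil assessments where
available, recommends the most beneficial farming practice per
category, and audits itself with redundancy, error-propagation and
aggregation-comparison diagnostics.

It is written for agronomists, soil-data services and researchers who
need a transparent, reproducible composite index over multi-year field
records — every threshold, weight and effectiveness value lives in
plain YAML configuration, and every score is traceable to the weights
that produced it.

## The model

**Indicators.** Each configured soil function (nitrogen supply,
aggregate stability, soil-life activity, …) is graded by an evaluation
curve keyed by soil type × land use. For nutrient-like functions the
curve is anchored agronomically: indicator value 1 at the optimum
level above which yield no longer responds, 0.5 at the level below
which additional fertilization is advised, piecewise-linear between
anchors. Optimum-window (e.g. pH) and categorical-lookup
(e.g. drought/wetness stress from the groundwater class) shapes cover
the rest. Scores are interpreted as good (> 0.75), sufficient
(0.5–0.75) or poor (< 0.5). Missing measurements propagate as missing
indicators, never as zero.

**Aggregation.** Three weighted steps with one correction factor each:

1. within category *k*, per year:
   `S_k = Σ w_i I_i / Σ w_i` with `w_i = 1/(I_i + c)`, `c = 0.2` —
   following von Liebig's law of the minimum, the poorest (most
   limiting) function weighs most;
2. across years: weighted mean with weight 1.0 for recent years
   (age < 5) and 0.5 for older years;
3. across the five categories (chemical, physical, biological,
   environmental, management):
   `S = Σ W_k S_k / Σ W_k` with `W_k = log2(n_k + 1)`, where `n_k` is
   the number of indicators backing the category.

All three weighting rules are configurable defaults. Every aggregate
is idempotent (constant input v ⇒ output v), monotone in each
indicator, and bounded by its inputs.

**Visual soil assessment (VSA).** A nine-item spade test (earthworms,
compaction, gray spots, ponding, cracks, bio pores, rooting depth,
structure, crop cover; each poor/moderate/good). When present, the
compaction and structure observations replace the model-derived
subsoil-compaction and aggregate-stability indicators.

**Advice.** Practices (liming, compost, non-till, …, repairing subsoil
compaction) are ranked per category by
`benefit(p) = Σ_f e(p, f) · (1 − I_f)` — effectiveness times remaining
deficiency — after filtering by land-use/soil-type applicability.

The shipped curve parameters and effectiveness matrix are
**illustrative defaults**, not an authoritative national calibration;
real deployments supply their own battery YAML.

## Worked example

```bash
soilscore simulate --n 5 --seed 2 --out demo.csv
soilscore score --input demo.csv --out-prefix demo
head -3 demo_scores.csv
```

```
field_id,score_chemical,n_chemical,score_physical,n_physical,score_biological,n_biological,score_environmental,n_environmental,score_management,n_management,final_score,score_class
field_00000,0.767404,9,0.736992,8,0.945046,2,0.853481,2,0.495206,1,0.772036,good
field_00001,0.798841,9,0.655667,8,0.949885,2,0.815053,2,0.664291,1,0.768517,good
```

Field `field_00000` scores 0.77 overall (class *good*): its chemistry
(0.77 from 9 indicators) and physics (0.74 from 8) are adequate,
biology is strong (0.95), and the management sub-score (0.50) is its
weakest aspect. `demo_scores.json` additionally records every weight
used. Asking for advice:

```bash
soilscore recommend --input demo.csv --out-prefix demo
head -3 demo_recommendations.csv
```

```
field_id,category,best_practice,benefit,note
field_00000,chemical,M8,1.13309,
field_00000,physical,M11,0.523865,
```

For this field the nutrient-status deficits are best addressed by
maintenance-and-build-up fertilization (M8), the physical deficit by
repairing subsoil compaction (M11).

The same pipeline is available as a library
(`soilscore.score_field`, `soilscore.evaluate_battery`,
`soilscore.recommend_all`, …) and the diagnostics via
`soilscore diagnose`.

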