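"""Three-step weighted aggregation from indicators to a final score.

Step 1 aggregates the indicators within each category for one year with
distance-to-target weights ``w = 1/(I + c)``: following the law of the
minimum, the poorest-scoring function (the presumed limiting factor for
crop production) weighs most. Step 2 aggregates each category's yearly
scores across the record's years, down-weighting older years. Step 3
aggregates the category sub-scores with weights growing in the number
of contributing indicators, ``W = log2(n + 1)``: a category backed by
more measured functions is better supported and weighs more.

All three weighting rules are configurable defaults, not authoritative
constants. Missing indicators (or whole missing category-years) are
excluded and the remaining weights renormalize; they are never read
as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Mapping, Sequence

from .errors import ConfigurationError, InputError
from .evaluation import (
    Battery,
    IndicatorVector,
    ScoreClass,
    classify_score,
    evaluate_battery,
)
from .types import Category, FieldYearRecord, validate_field_records

__all__ = [
    "AggregationConfig",
    "CategoryScore",
    "ScoreReport",
    "weight_distance_to_target",
    "aggregate_within_category",
    "aggregate_years",
    "weight_category",
    "aggregate_categories",
    "score_field",
    "score_fields",
]


@dataclass
class AggregationConfig:
    """Tunable weighting parameters for the three aggregation steps.

    ``c``
        Distance-to-target offset in ``w = 1/(I + c)``; smaller values
        emphasize the limiting factor more strongly. Default 0.2.
    ``recent_weight`` / ``old_weight`` / ``recent_horizon``
        Step-2 year weights: years younger than ``recent_horizon``
        (default 5) get ``recent_weight`` (1.0), older years
        ``old_weight`` (0.5).
    ``category_weight_rule``
        Step-3 weight as a function of the category's indicator count;
        default ``log2(n + 1)``.
    ``include_management``
        Whether the management category enters the final score.
    """

    c: float = 0.2
    recent_weight: float = 1.0
    old_weight: float = 0.5
    recent_horizon: int = 5
    category_weight_rule: Callable[[int], float] | None = None
    include_management: bool = True

    def validate(self) -> None:
        if not (self.c > 0):
            raise ConfigurationError(f"distance-to-target offset c={self.c} must be > 0")
        if self.recent_weight <= 0 or self.old_weight <= 0:
            raise ConfigurationError("year weights must be positive")
        if self.recent_horizon < 0:
            raise ConfigurationError("recent_horizon must be >= 0")

    def year_weight(self, age: int) -> float:
        return self.recent_weight if age < self.recent_horizon else self.old_weight

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "AggregationConfig":
        known = {
            "c", "recent_weight", "old_weight", "recent_horizon",
            "include_management",
        }
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown aggregation keys: {sorted(unknown)}")
        cfg = cls(**{k: d[k] for k in known & set(d)})
        cfg.validate()
        return cfg


def weight_distance_to_target(value: float, c: float = 0.2) -> float:
    """Step-1 weight ``w = 1/(I + c)``: strictly decreasing in the
    indicator value, so the most limiting function weighs most."""
    if not (c > 0):
        raise ConfigurationError(f"distance-to-target offset c={c} must be > 0")
    if not (0.0 <= value <= 1.0):
        raise InputError(f"indicator value {value} outside [0, 1]")
    return 1.0 / (value + c)


def aggregate_within_category(
    values: Iterable[float | None], cfg: AggregationConfig | None = None
) -> float | None:
    """Step 1: distance-to-target weighted mean of one category's
    indicator values for one year; missing values are excluded. Returns
    ``None`` (not 0) when nothing is present."""
    cfg = cfg or AggregationConfig()
    present = [v for v in values if v is not None]
    if not present:
        return None
    weights = [weight_distance_to_target(v, cfg.c) for v in present]
    return _weighted_mean(present, weights)


def aggregate_years(
    scores_by_age: Mapping[int, float | None], cfg: AggregationConfig | None = None
) -> float | None:
    """Step 2: recency-weighted mean of one category's yearly scores;
    missing years are excluded and weights renormalize."""
    cfg = cfg or AggregationConfig()
    pairs = [(age, s) for age, s in scores_by_age.items() if s is not None]
    if not pairs:
        return None
    values = [s for _, s in pairs]
    weights = [cfg.year_weight(age) for age, _ in pairs]
    return _weighted_mean(values, weights)


def weight_category(n: int, cfg: AggregationConfig | None = None) -> float:
    """Step-3 weight, default ``log2(n + 1)``: zero only for an empty
    category, growing with diminishing returns in the indicator count."""
    if n < 0:
        raise InputError(f"indicator count {n} is negative")
    rule = (cfg.category_weight_rule if cfg else None) or (lambda k: math.log2(k + 1))
    return rule(n)


@dataclass
class CategoryScore:
    """A category sub-score with its contributing-indicator count."""

    score: float | None
    n: int = 0


def aggregate_categories(
    category_scores: Mapping[Category, CategoryScore],
    cfg: AggregationConfig | None = None,
) -> float:
    """Step 3: indicator-count weighted mean of the category sub-scores.
    Management is skipped when ``cfg.include_management`` is false."""
    cfg = cfg or AggregationConfig()
    values: list[float] = []
    weights: list[float] = []
    for cat, cs in category_scores.items():
        if cat is Category.MANAGEMENT and not cfg.include_management:
            continue
        if cs.score is None or cs.n < 1:
            continue
        values.append(cs.score)
        weights.append(weight_category(cs.n, cfg))
    if not values:
        raise InputError("no category has a score; cannot aggregate")
    return _weighted_mean(values, weights)


def _weighted_mean(values: Sequence[float], weights: Sequence[float]) -> float:
    total = sum(weights)
    m = sum(w * v for v, w in zip(values, weights)) / total
    # exact-arithmetic bound; clip float dust so invariants hold verbatim
    return min(max(m, min(values)), max(values))


@dataclass
class ScoreReport:
    """Full provenance of one field's score: per-year category scores,
    aggregated sub-scores, final score, class, and all weights used."""

    field_id: str
    per_year: dict[int, dict[Category, CategoryScore]]
    category_scores: dict[Category, CategoryScore]
    final_score: float
    score_class: ScoreClass
    weights: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "field_id": self.field_id,
            "per_year": {
                str(age): {
                    cat.value: {"score": cs.score, "n": cs.n}
                    for cat, cs in cats.items()
                }
                for age, cats in sorted(self.per_year.items())
            },
            "category_scores": {
                cat.value: {"score": cs.score, "n": cs.n}
                for cat, cs in self.category_scores.items()
            },
            "final_score": self.final_score,
            "score_class": self.score_class.value,
            "weights": self.weights,
        }

    def to_flat_row(self) -> dict[str, Any]:
        row: dict[str, Any] = {"field_id": self.field_id}
        for cat in Category:
            cs = self.category_scores.get(cat, CategoryScore(None, 0))
            row[f"score_{cat.value}"] = cs.score
            row[f"n_{cat.value}"] = cs.n
        row["final_score"] = self.final_score
        row["score_class"] = self.score_class.value
        return row


def _indicator_vectors_for_field(
    records: Sequence[FieldYearRecord], battery: Battery
) -> dict[int, IndicatorVector]:
    from .advisory import apply_vsa  # local import: advisory builds on evaluation

    vectors: dict[int, IndicatorVector] = {}
    for rec in records:
        vec = evaluate_battery(battery, rec)
        vec = apply_vsa(vec, rec.vsa)
        vectors[rec.year_age] = vec
    return vectors


def score_field(
    records: Sequence[FieldYearRecord],
    battery: Battery,
    cfg: AggregationConfig | None = None,
    *,
    validate: bool = True,
) -> ScoreReport:
    """Score one field from its multi-year records.

    Evaluates the battery per year (substituting VSA observations where
    supplied), then runs the three aggregation steps and classifies the
    final score.
    """
    cfg = cfg or AggregationConfig()
    cfg.validate()
    if validate:
        validate_field_records(list(records))
    vectors = _indicator_vectors_for_field(records, battery)

    per_year: dict[int, dict[Category, CategoryScore]] = {}
    indicator_weights: dict[int, dict[str, float]] = {}
    for age, vec in vectors.items():
        cats: dict[Category, CategoryScore] = {}
        w_used: dict[str, float] = {}
        for cat in Category:
            vals = [
                iv.value for iv in vec.values() if iv.category is cat
            ]
            present = [v for v in vals if v is not None]
            cats[cat] = CategoryScore(
                aggregate_within_category(vals, cfg), len(present)
            )
        for iv in vec.values():
            if iv.value is not None:
                w_used[iv.function_id] = weight_distance_to_target(iv.value, cfg.c)
        per_year[age] = cats
        indicator_weights[age] = w_used

    category_scores: dict[Category, CategoryScore] = {}
    for cat in Category:
        by_age = {age: cats[cat].score for age, cats in per_year.items()}
        # n = distinct functions contributing in at least one year
        contributing: set[str] = set()
        for age, vec in vectors.items():
            contributing |= {
                fid for fid, iv in vec.items()
                if iv.category is cat and iv.value is not None
            }
        category_scores[cat] = CategoryScore(aggregate_years(by_age, cfg), len(contributing))

    final = aggregate_categories(category_scores, cfg)
    weights = {
        "c": cfg.c,
        "year_weights": {
            age: cfg.year_weight(age) for age in sorted(per_year)
        },
        "category_weights": {
            cat.value: weight_category(cs.n, cfg)
            for cat, cs in category_scores.items()
            if cs.score is not None and cs.n >= 1
            and (cfg.include_management or cat is not Category.MANAGEMENT)
        },
        "indicator_weights": {
            str(age): w for age, w in sorted(indicator_weights.items())
        },
        "include_management": cfg.include_management,
    }
    return ScoreReport(
        field_id=records[0].field_id,
        per_year=per_year,
        category_scores=category_scores,
        final_score=final,
        score_class=classify_score(final),
        weights=weights,
    )


def score_fields(
    records: Sequence[FieldYearRecord],
    battery: Battery,
    cfg: AggregationConfig | None = None,
    *,
    validate: bool = True,
) -> list[ScoreReport]:
    """Group records by field_id (input order preserved) and score each."""
    by_field: dict[str, list[FieldYearRecord]] = {}
    for rec in records:
        by_field.setdefault(rec.field_id, []).append(rec)
    return [
        score_field(recs, battery, cfg, validate=validate)
        for recs in by_field.values()
    ]
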