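"""Indicator battery: definitions, config loading, evaluation.

An *indicator battery* is the configured list of soil functions to
grade. Each :class:`IndicatorDefinition` names the properties it needs,
the category it belongs to (chemical, physical, biological,
environmental, management) and one evaluation curve per stratum
(soil type x land use), with ``*`` wildcards for either axis.

The shipped default battery (``data/battery.yaml``) carries
*illustrative, non-authoritative* curve parameters: the authoritative
national threshold tables live in fertilizer-recommendation knowledge
bases and are not reproduced here. Every parameter is overridable by
supplying a different battery file.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterable

import yaml

from .curves import EvaluationCurveSpec
from .errors import ConfigurationError, InputError
from .types import (
    Category,
    FieldYearRecord,
    LandUse,
    SoilType,
    PROPERTY_NAMES,
)

__all__ = [
    "IndicatorSource",
    "IndicatorDefinition",
    "IndicatorValue",
    "IndicatorVector",
    "Battery",
    "load_battery",
    "default_battery",
    "evaluate_indicator",
    "evaluate_battery",
    "classify_score",
    "ScoreClass",
]

#: Context-derived pseudo-properties an indicator may require, in
#: addition to the measured profile properties.
CONTEXT_PROPERTIES = ("soil_type", "land_use", "groundwater_class", "crop_code")
MANAGEMENT_PROPERTY = "management_score"


class IndicatorSource(str, enum.Enum):
    MEASURED_CURVE = "measured_curve"
    VSA = "vsa"
    CONFIG = "config"


class ScoreClass(str, enum.Enum):
    GOOD = "good"
    SUFFICIENT = "sufficient"
    POOR = "poor"


def classify_score(s: float) -> ScoreClass:
    """Interpret a 0-1 score: good (>0.75), sufficient (0.5-0.75),
    poor (<0.5); both boundaries belong to the sufficient class."""
    if not (isinstance(s, (int, float)) and 0.0 <= s <= 1.0):
        raise InputError(f"score {s!r} outside [0, 1]")
    if s > 0.75:
        return ScoreClass.GOOD
    if s >= 0.5:
        return ScoreClass.SUFFICIENT
    return ScoreClass.POOR


@dataclass
class IndicatorDefinition:
    """Configuration of one soil function's indicator."""

    function_id: str
    category: Category
    required_properties: tuple[str, ...]
    curve_by_stratum: dict[str, EvaluationCurveSpec]
    vsa_substitutable: bool = False
    label: str = ""

    def validate(self) -> None:
        if not self.function_id:
            raise ConfigurationError("indicator with empty function_id")
        if not isinstance(self.category, Category):
            raise ConfigurationError(
                f"{self.function_id}: unknown category {self.category!r}"
            )
        valid = set(PROPERTY_NAMES) | set(CONTEXT_PROPERTIES) | {MANAGEMENT_PROPERTY}
        for p in self.required_properties:
            if p not in valid:
                raise ConfigurationError(
                    f"{self.function_id}: unknown required property {p!r}"
                )
        if not self.curve_by_stratum:
            raise ConfigurationError(f"{self.function_id}: no curves configured")
        for key, spec in self.curve_by_stratum.items():
            _parse_stratum_key(key, self.function_id)
            spec.validate(self.function_id)

    def curve_for(self, soil_type: SoilType, land_use: LandUse) -> EvaluationCurveSpec:
        """Resolve the curve for a stratum: exact key, then soil-only,
        land-use-only, then the ``*:*`` fallback."""
        for key in (
            f"{soil_type.value}:{land_use.value}",
            f"{soil_type.value}:*",
            f"*:{land_use.value}",
            "*:*",
        ):
            if key in self.curve_by_stratum:
                return self.curve_by_stratum[key]
        raise ConfigurationError(
            f"{self.function_id}: no curve for stratum "
            f"{soil_type.value} x {land_use.value}"
        )


@dataclass
class IndicatorValue:
    """One evaluated indicator: 0-1 value or missing (``None``)."""

    function_id: str
    category: Category
    value: float | None
    source: IndicatorSource = IndicatorSource.MEASURED_CURVE


#: An evaluated battery for one field-year, keyed by function_id.
IndicatorVector = dict[str, IndicatorValue]


@dataclass
class Battery:
    """A validated list of indicator definitions."""

    definitions: list[IndicatorDefinition] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for d in self.definitions:
            if d.function_id in seen:
                raise ConfigurationError(f"duplicate function_id {d.function_id!r}")
            seen.add(d.function_id)
            d.validate()
        # chemical, physical and biological each need >= 2 functions for
        # the assessment to be considered minimally balanced
        for cat in (Category.CHEMICAL, Category.PHYSICAL, Category.BIOLOGICAL):
            n = sum(1 for d in self.definitions if d.category is cat)
            if n < 2:
                raise ConfigurationError(
                    f"battery has only {n} {cat.value} function(s); "
                    "chemical, physical and biological each require at least 2"
                )

    def __iter__(self) -> Iterable[IndicatorDefinition]:
        return iter(self.definitions)

    def __len__(self) -> int:
        return len(self.definitions)

    def __getitem__(self, function_id: str) -> IndicatorDefinition:
        for d in self.definitions:
            if d.function_id == function_id:
                return d
        raise KeyError(function_id)

    def function_ids(self, *, include_management: bool = True) -> list[str]:
        return [
            d.function_id
            for d in self.definitions
            if include_management or d.category is not Category.MANAGEMENT
        ]


def _parse_stratum_key(key: str, function_id: str) -> tuple[str, str]:
    parts = key.split(":")
    if len(parts) != 2:
        raise ConfigurationError(
            f"{function_id}: stratum key {key!r} is not 'soil_type:land_use'"
        )
    soil, lu = parts
    if soil != "*" and soil not in {s.value for s in SoilType}:
        raise ConfigurationError(f"{function_id}: unknown soil type in key {key!r}")
    if lu != "*" and lu not in {u.value for u in LandUse}:
        raise ConfigurationError(f"{function_id}: unknown land use in key {key!r}")
    return soil, lu


def _definition_from_dict(entry: dict[str, Any], where: str) -> IndicatorDefinition:
    try:
        function_id = entry["function_id"]
        category = Category(entry["category"])
        required = tuple(entry.get("required_properties", ()))
        curves_raw = entry["curves"]
    except KeyError as exc:
        raise ConfigurationError(f"{where}: missing key {exc}") from None
    except ValueError:
        raise ConfigurationError(
            f"{where}: unknown category {entry.get('category')!r}"
        ) from None
    if not isinstance(curves_raw, dict):
        raise ConfigurationError(f"{where}: 'curves' must be a mapping")
    curves: dict[str, EvaluationCurveSpec] = {}
    for key, spec in curves_raw.items():
        if not isinstance(spec, dict) or "kind" not in spec:
            raise ConfigurationError(
                f"{where}: curve for stratum {key!r} must be a mapping with 'kind'"
            )
        params = {k: v for k, v in spec.items() if k != "kind"}
        curves[str(key)] = EvaluationCurveSpec(kind=spec["kind"], parameters=params)
    return IndicatorDefinition(
        function_id=function_id,
        category=category,
        required_properties=required,
        curve_by_stratum=curves,
        vsa_substitutable=bool(entry.get("vsa_substitutable", False)),
        label=str(entry.get("label", "")),
    )


def load_battery(source: str | Path | dict[str, Any]) -> Battery:
    """Load and strictly validate a battery from a YAML/JSON file or an
    already-parsed mapping; errors name the offending entry."""
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        origin = str(source)
    else:
        raw, origin = source, "<mapping>"
    if not isinstance(raw, dict) or "battery" not in raw:
        raise ConfigurationError(f"{origin}: expected a top-level 'battery' list")
    entries = raw["battery"]
    if not isinstance(entries, list) or not entries:
        raise ConfigurationError(f"{origin}: 'battery' must be a non-empty list")
    defs = []
    for i, entry in enumerate(entries):
        where = f"{origin}: battery[{i}]"
        if not isinstance(entry, dict):
            raise ConfigurationError(f"{where}: entry must be a mapping")
        defs.append(_definition_from_dict(entry, where))
    return Battery(defs)


def default_battery() -> Battery:
    """The shipped illustrative battery (22 soil functions)."""
    ref = resources.files("soilscore.data").joinpath("battery.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return load_battery(yaml.safe_load(fh))


def _extract_property(name: str, rec: FieldYearRecord) -> Any:
    """Fetch a required property from profile, context or management."""
    if name in PROPERTY_NAMES:
        return getattr(rec.profile, name)
    if name == "groundwater_class":
        return rec.context.groundwater_class.value
    if name == "soil_type":
        return rec.context.soil_type.value
    if name == "land_use":
        return rec.context.land_use.value
    if name == "crop_code":
        return rec.context.crop_code or None
    if name == MANAGEMENT_PROPERTY:
        return rec.management.score if rec.management is not None else None
    raise ConfigurationError(f"unknown property {name!r}")


def evaluate_indicator(
    defn: IndicatorDefinition, rec: FieldYearRecord
) -> IndicatorValue:
    """Evaluate one soil function for one field-year.

    Returns a missing value (``value=None``) — never 0 — when any
    required property is absent from the record.
    """
    values = [_extract_property(p, rec) for p in defn.required_properties]
    source = (
        IndicatorSource.CONFIG
        if defn.category is Category.MANAGEMENT
        else IndicatorSource.MEASURED_CURVE
    )
    if any(v is None for v in values) or not values:
        return IndicatorValue(defn.function_id, defn.category, None, source)
    curve = defn.curve_for(rec.context.soil_type, rec.context.land_use)
    # curves are univariate: the first required property drives the curve
    score = curve.evaluate(values[0], function_id=defn.function_id)
    return IndicatorValue(defn.function_id, defn.category, score, source)


def evaluate_battery(battery: Battery, rec: FieldYearRecord) -> IndicatorVector:
    """Evaluate every configured soil function for one field-year."""
    return {
        d.function_id: evaluate_indicator(d, rec) for d in battery.definitions
    }
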