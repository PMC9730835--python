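"""Domain types: soil profiles, field context, per-field-year records.

A *field-year record* is the atomic unit of input: the measured topsoil
profile of one field in one year, plus the field context (soil type,
groundwater class, land use) and, optionally, a management record and a
nine-item visual soil assessment (VSA).

Missing measurements are represented as ``None`` (never 0); downstream
evaluation propagates them as missing indicators.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields

from .errors import InputError

__all__ = [
    "SoilType",
    "LandUse",
    "GroundwaterClass",
    "Category",
    "VSARating",
    "SoilProfile",
    "FieldContext",
    "ManagementRecord",
    "VSARecord",
    "FieldYearRecord",
    "PROPERTY_NAMES",
    "VSA_ITEMS",
]


class SoilType(str, enum.Enum):
    SAND = "sand"
    CLAY = "clay"
    LOESS = "loess"
    PEAT = "peat"


class LandUse(str, enum.Enum):
    GRASSLAND = "grassland"
    MAIZE = "maize"
    ARABLE = "arable"


class GroundwaterClass(str, enum.Enum):
    """Ordinal groundwater classes, shallow (I) to deep (VIII)."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"
    VI = "VI"
    VII = "VII"
    VIII = "VIII"

    @property
    def depth_rank(self) -> int:
        return list(GroundwaterClass).index(self)


class Category(str, enum.Enum):
    CHEMICAL = "chemical"
    PHYSICAL = "physical"
    BIOLOGICAL = "biological"
    ENVIRONMENTAL = "environmental"
    MANAGEMENT = "management"


class VSARating(str, enum.Enum):
    POOR = "poor"
    MODERATE = "moderate"
    GOOD = "good"


def _finite_or_none(name: str, v: float | None, problems: list[str]) -> None:
    if v is not None and not math.isfinite(v):
        problems.append(f"{name} is not finite")


@dataclass
class SoilProfile:
    """Measured topsoil properties of one field-year.

    Units: ``organic_matter`` mass % of dry soil; ``ph`` unitless;
    ``clay``/``silt``/``sand`` mass %; nutrient pools mg/kg;
    ``cec`` mmol+/kg; CEC occupancies % of CEC; ``pmn`` mg N/kg
    (potentially mineralizable N); ``bulk_density`` g/cm3.
    Any property may be ``None`` (not measured).
    """

    organic_matter: float | None = None
    ph: float | None = None
    clay: float | None = None
    silt: float | None = None
    sand: float | None = None
    n_total: float | None = None
    p_avail: float | None = None
    k_avail: float | None = None
    mg_avail: float | None = None
    cu_avail: float | None = None
    s_avail: float | None = None
    zn_avail: float | None = None
    cec: float | None = None
    cec_occupancy_ca: float | None = None
    cec_occupancy_mg: float | None = None
    cec_occupancy_k: float | None = None
    pmn: float | None = None
    bulk_density: float | None = None

    def validate(self) -> None:
        """Raise :class:`InputError` listing every violated invariant."""
        problems: list[str] = []
        for f in fields(self):
            _finite_or_none(f.name, getattr(self, f.name), problems)
        if problems:
            raise InputError("; ".join(problems))

        if self.ph is not None and not (2.0 <= self.ph <= 11.0):
            problems.append(f"ph={self.ph} outside [2, 11]")
        for name in ("clay", "silt", "sand"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                problems.append(f"{name}={v} outside [0, 100]")
        if None not in (self.clay, self.silt, self.sand):
            total = self.clay + self.silt + self.sand  # type: ignore[operator]
            if not (99.0 <= total <= 101.0):
                problems.append(f"clay+silt+sand={total:.3f} outside [99, 101]")
        nonneg = (
            "organic_matter", "n_total", "p_avail", "k_avail", "mg_avail",
            "cu_avail", "s_avail", "zn_avail", "cec", "pmn", "bulk_density",
            "cec_occupancy_ca", "cec_occupancy_mg", "cec_occupancy_k",
        )
        for name in nonneg:
            v = getattr(self, name)
            if v is not None and v < 0:
                problems.append(f"{name}={v} is negative")
        if problems:
            raise InputError("; ".join(problems))


#: Names of all measured properties, in canonical column order.
PROPERTY_NAMES: tuple[str, ...] = tuple(f.name for f in fields(SoilProfile))


@dataclass
class FieldContext:
    """Field context for one year: soil type, hydrology and land use."""

    soil_type: SoilType
    groundwater_class: GroundwaterClass
    land_use: LandUse
    crop_code: str = ""

    def validate(self) -> None:
        if not isinstance(self.soil_type, SoilType):
            raise InputError(f"unknown soil_type {self.soil_type!r}")
        if not isinstance(self.groundwater_class, GroundwaterClass):
            raise InputError(f"unknown groundwater_class {self.groundwater_class!r}")
        if not isinstance(self.land_use, LandUse):
            raise InputError(f"unknown land_use {self.land_use!r}")


@dataclass
class ManagementRecord:
    """Management information; ``score`` is an externally supplied 0-1
    sub-score (e.g. from a sustainable-management labelling scheme)."""

    score: float
    flags: dict[str, bool] = field(default_factory=dict)

    def validate(self) -> None:
        if not (isinstance(self.score, (int, float)) and 0.0 <= self.score <= 1.0):
            raise InputError(f"management score {self.score!r} outside [0, 1]")


#: The nine visually assessed items, in reporting order.
VSA_ITEMS: tuple[str, ...] = (
    "earthworms",
    "compaction",
    "gray_spots",
    "ponding",
    "cracks",
    "bio_pores",
    "rooting_depth",
    "structure",
    "crop_cover",
)


@dataclass
class VSARecord:
    """Nine-item visual soil assessment, each rated poor/moderate/good."""

    earthworms: VSARating
    compaction: VSARating
    gray_spots: VSARating
    ponding: VSARating
    cracks: VSARating
    bio_pores: VSARating
    rooting_depth: VSARating
    structure: VSARating
    crop_cover: VSARating

    def validate(self) -> None:
        for item in VSA_ITEMS:
            r = getattr(self, item)
            if not isinstance(r, VSARating):
                raise InputError(f"VSA item {item!r} has invalid rating {r!r}")

    def items(self) -> dict[str, VSARating]:
        return {item: getattr(self, item) for item in VSA_ITEMS}


@dataclass
class FieldYearRecord:
    """One field in one year: profile + context + optional extras.

    ``year_age`` counts back from the most recent year: 0 is the latest
    year on record, 9 the oldest in a 10-year history.
    """

    field_id: str
    year_age: int
    profile: SoilProfile
    context: FieldContext
    management: ManagementRecord | None = None
    vsa: VSARecord | None = None

    def validate(self) -> None:
        if not self.field_id:
            raise InputError("field_id must be non-empty")
        if not (0 <= self.year_age <= 9):
            raise InputError(
                f"field {self.field_id}: year_age={self.year_age} outside [0, 9]"
            )
        try:
            self.profile.validate()
            self.context.validate()
            if self.management is not None:
                self.management.validate()
            if self.vsa is not None:
                self.vsa.validate()
        except InputError as exc:
            raise InputError(
                f"field {self.field_id}, year_age {self.year_age}: {exc}"
            ) from None


def validate_field_records(records: list[FieldYearRecord]) -> None:
    """Validate a group of records that should form one field."""
    if not records:
        raise InputError("no records supplied")
    ids = {r.field_id for r in records}
    if len(ids) != 1:
        raise InputError(f"records span multiple field_ids: {sorted(ids)}")
    ages = [r.year_age for r in records]
    if len(set(ages)) != len(ages):
        raise InputError(f"field {records[0].field_id}: duplicate year_age values")
    if len(records) > 10:
        raise InputError(f"field {records[0].field_id}: more than 10 years supplied")
    for r in records:
        r.validate()
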