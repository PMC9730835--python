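"""Reproducible synthetic field-year records.

The generator emulates Dutch-style multi-year field records: per-field
topsoil properties drawn from truncated normal distributions
parameterized by soil type, a persistent land-use rotation (Markov
chain whose stationary distribution is the configured mix), ordinal
groundwater classes typical for each soil type, an optional management
sub-score, and an optional nine-item visual assessment. A latent
per-field quality factor correlates the quality-linked properties
(organic matter, soil life, bulk density) so that fields differ
coherently, the way good and poor fields do in practice.

Paired mode produces good/poor field pairs sharing soil type, land use
and hydrology; the poor member's physically and biologically linked
properties are shifted a configurable fraction (``pair_offset``) of the
way toward their deficient bound, so the whole pipeline — evaluation
curves included — is exercised, not just the aggregation.

All draws derive from a single :func:`numpy.random.default_rng` seed;
identical configuration + seed gives identical records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml
from scipy.special import ndtr, ndtri

from .errors import ConfigurationError
from .types import (
    FieldContext,
    FieldYearRecord,
    GroundwaterClass,
    LandUse,
    ManagementRecord,
    SoilProfile,
    SoilType,
    VSARating,
    VSARecord,
    VSA_ITEMS,
)

__all__ = [
    "TruncNormSpec",
    "SimulationConfig",
    "generate_fields",
    "generate_pairs",
    "generate_rotation",
]


@dataclass(frozen=True)
class TruncNormSpec:
    """Truncated normal: mean, sd and hard truncation bounds."""

    mean: float
    sd: float
    lo: float
    hi: float

    def validate(self, name: str) -> None:
        if self.sd < 0:
            raise ConfigurationError(f"{name}: sd must be >= 0")
        if not (self.lo < self.hi):
            raise ConfigurationError(f"{name}: lo must be < hi")


def _truncnorm(rng: np.random.Generator, spec: TruncNormSpec,
               mean: float | None = None, sd: float | None = None,
               size: int | None = None):
    """Exact truncated-normal draw via inverse-CDF sampling."""
    mu = spec.mean if mean is None else mean
    s = spec.sd if sd is None else sd
    if s == 0:
        x = np.full(size or 1, mu)
        return float(x[0]) if size is None else x
    a, b = ndtr((spec.lo - mu) / s), ndtr((spec.hi - mu) / s)
    u = rng.uniform(a, b, size=size or 1)
    x = np.clip(mu + s * ndtri(u), spec.lo, spec.hi)
    return float(x[0]) if size is None else x


# Signed loading of the latent field-quality factor on each property:
# +1 means a better field has more of it, -1 less. Unlisted properties
# are quality-neutral.
QUALITY_LOADINGS: dict[str, float] = {
    "organic_matter": 1.0,
    "pmn": 1.0,
    "bulk_density": -1.0,
    "p_avail": 0.3,
    "k_avail": 0.3,
}

# Properties shifted toward deficiency in the "poor" member of a pair
# (physically / biologically linked), with the deficient bound side.
PAIR_DEFICIENCY_SIDE: dict[str, str] = {
    "organic_matter": "lo",
    "pmn": "lo",
    "bulk_density": "hi",
}

_D = TruncNormSpec  # brevity in the tables below

#: Illustrative per-soil-type property distributions (units as in
#: :class:`~soilscore.types.SoilProfile`).
DEFAULT_PROPERTY_MODELS: dict[SoilType, dict[str, TruncNormSpec]] = {
    SoilType.SAND: {
        "organic_matter": _D(4.5, 1.5, 1.0, 12.0),
        "ph": _D(5.4, 0.4, 4.0, 7.0),
        "clay": _D(4.0, 2.0, 0.5, 10.0),
        "silt": _D(12.0, 5.0, 2.0, 30.0),
        "n_total": _D(1500, 500, 300, 4000),
        "p_avail": _D(45, 15, 5, 120),
        "k_avail": _D(120, 40, 20, 300),
        "mg_avail": _D(85, 30, 10, 250),
        "cu_avail": _D(3.0, 1.2, 0.3, 8.0),
        "s_avail": _D(15, 7, 2, 50),
        "zn_avail": _D(5.0, 2.0, 0.5, 15.0),
        "cec": _D(80, 30, 20, 200),
        "pmn": _D(60, 25, 5, 180),
        "bulk_density": _D(1.45, 0.10, 1.10, 1.75),
    },
    SoilType.CLAY: {
        "organic_matter": _D(3.5, 1.2, 1.0, 10.0),
        "ph": _D(7.0, 0.5, 5.5, 8.2),
        "clay": _D(30.0, 8.0, 12.0, 50.0),
        "silt": _D(40.0, 8.0, 15.0, 60.0),
        "n_total": _D(1800, 500, 400, 4500),
        "p_avail": _D(40, 14, 5, 110),
        "k_avail": _D(160, 45, 30, 350),
        "mg_avail": _D(120, 35, 20, 300),
        "cu_avail": _D(4.0, 1.4, 0.5, 9.0),
        "s_avail": _D(18, 7, 3, 55),
        "zn_avail": _D(5.5, 2.0, 0.5, 15.0),
        "cec": _D(200, 60, 60, 400),
        "pmn": _D(80, 30, 10, 220),
        "bulk_density": _D(1.30, 0.10, 1.00, 1.65),
    },
    SoilType.LOESS: {
        "organic_matter": _D(2.5, 0.8, 0.8, 7.0),
        "ph": _D(6.5, 0.4, 5.2, 7.8),
        "clay": _D(15.0, 4.0, 6.0, 28.0),
        "silt": _D(60.0, 8.0, 40.0, 80.0),
        "n_total": _D(1400, 400, 300, 3500),
        "p_avail": _D(42, 14, 5, 110),
        "k_avail": _D(140, 40, 25, 320),
        "mg_avail": _D(100, 30, 15, 260),
        "cu_avail": _D(3.5, 1.2, 0.4, 8.5),
        "s_avail": _D(16, 6, 2, 50),
        "zn_avail": _D(5.0, 1.8, 0.5, 14.0),
        "cec": _D(140, 40, 40, 300),
        "pmn": _D(70, 25, 8, 200),
        "bulk_density": _D(1.40, 0.09, 1.10, 1.70),
    },
    SoilType.PEAT: {
        "organic_matter": _D(22.0, 6.0, 8.0, 45.0),
        "ph": _D(5.2, 0.4, 4.0, 6.5),
        "clay": _D(15.0, 6.0, 2.0, 35.0),
        "silt": _D(30.0, 8.0, 10.0, 50.0),
        "n_total": _D(9000, 2500, 3000, 18000),
        "p_avail": _D(38, 14, 5, 110),
        "k_avail": _D(110, 35, 20, 280),
        "mg_avail": _D(130, 40, 20, 320),
        "cu_avail": _D(3.5, 1.3, 0.4, 9.0),
        "s_avail": _D(25, 9, 4, 70),
        "zn_avail": _D(5.5, 2.2, 0.5, 16.0),
        "cec": _D(250, 70, 80, 500),
        "pmn": _D(160, 50, 30, 400),
        "bulk_density": _D(1.00, 0.12, 0.70, 1.40),
    },
}

DEFAULT_SOIL_TYPE_MIX: dict[SoilType, float] = {
    SoilType.SAND: 0.45,
    SoilType.CLAY: 0.35,
    SoilType.LOESS: 0.08,
    SoilType.PEAT: 0.12,
}

DEFAULT_LAND_USE_MIX: dict[SoilType, dict[LandUse, float]] = {
    SoilType.SAND: {LandUse.GRASSLAND: 0.45, LandUse.MAIZE: 0.30, LandUse.ARABLE: 0.25},
    SoilType.CLAY: {LandUse.GRASSLAND: 0.40, LandUse.MAIZE: 0.10, LandUse.ARABLE: 0.50},
    SoilType.LOESS: {LandUse.GRASSLAND: 0.25, LandUse.MAIZE: 0.15, LandUse.ARABLE: 0.60},
    SoilType.PEAT: {LandUse.GRASSLAND: 0.90, LandUse.MAIZE: 0.05, LandUse.ARABLE: 0.05},
}

DEFAULT_GROUNDWATER: dict[SoilType, tuple[tuple[GroundwaterClass, float], ...]] = {
    SoilType.SAND: (
        (GroundwaterClass.IV, 0.15), (GroundwaterClass.V, 0.20),
        (GroundwaterClass.VI, 0.35), (GroundwaterClass.VII, 0.30),
    ),
    SoilType.CLAY: (
        (GroundwaterClass.II, 0.10), (GroundwaterClass.III, 0.25),
        (GroundwaterClass.IV, 0.30), (GroundwaterClass.V, 0.20),
        (GroundwaterClass.VI, 0.15),
    ),
    SoilType.LOESS: (
        (GroundwaterClass.VI, 0.20), (GroundwaterClass.VII, 0.40),
        (GroundwaterClass.VIII, 0.40),
    ),
    SoilType.PEAT: (
        (GroundwaterClass.I, 0.20), (GroundwaterClass.II, 0.50),
        (GroundwaterClass.III, 0.30),
    ),
}

_ARABLE_CROPS = ("potato", "winter_wheat", "sugar_beet", "onion", "barley")


@dataclass
class SimulationConfig:
    """Generator settings; defaults emulate a Dutch-style field mix."""

    n_fields: int = 100
    years: int = 10
    seed: int = 0
    soil_type_mix: dict[SoilType, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_SOIL_TYPE_MIX)
    )
    land_use_mix: dict[SoilType, dict[LandUse, float]] = dc_field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LAND_USE_MIX.items()}
    )
    persistence: float = 0.85
    property_models: dict[SoilType, dict[str, TruncNormSpec]] = dc_field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PROPERTY_MODELS.items()}
    )
    quality_sd: float = 0.5
    year_jitter: float = 0.05
    vsa_fraction: float = 0.3
    pair_offset: float = 0.2

    def validate(self) -> None:
        if self.n_fields < 0 or not (1 <= self.years <= 10):
            raise ConfigurationError("n_fields >= 0 and 1 <= years <= 10 required")
        total = sum(self.soil_type_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6) or any(
            p < 0 for p in self.soil_type_mix.values()
        ):
            raise ConfigurationError(
                f"soil_type_mix proportions must be >= 0 and sum to 1 (got {total})"
            )
        if not (0.0 <= self.persistence <= 1.0):
            raise ConfigurationError("persistence must be in [0, 1]")
        if not (0.0 <= self.pair_offset <= 1.0):
            raise ConfigurationError("pair_offset must be in [0, 1]")
        if not (0.0 <= self.vsa_fraction <= 1.0):
            raise ConfigurationError("vsa_fraction must be in [0, 1]")
        for st, props in self.property_models.items():
            for name, spec in props.items():
                spec.validate(f"{st.value}.{name}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "SimulationConfig":
        cfg = cls()
        simple = {
            "n_fields", "years", "seed", "persistence", "quality_sd",
            "year_jitter", "vsa_fraction", "pair_offset",
        }
        for key, val in raw.items():
            if key in simple:
                setattr(cfg, key, val)
            elif key == "soil_type_mix":
                cfg.soil_type_mix = {SoilType(k): float(v) for k, v in val.items()}
            elif key == "property_models":
                for st_name, props in val.items():
                    st = SoilType(st_name)
                    for pname, p in props.items():
                        cfg.property_models[st][pname] = TruncNormSpec(
                            float(p["mean"]), float(p["sd"]),
                            float(p["lo"]), float(p["hi"]),
                        )
            else:
                raise ConfigurationError(f"unknown simulation key {key!r}")
        cfg.validate()
        return cfg


def generate_rotation(
    years: int,
    land_use_mix: Mapping[LandUse, float],
    seed_or_rng: int | np.random.Generator,
    persistence: float = 0.85,
) -> list[LandUse]:
    """Persistent land-use Markov chain, index 0 = most recent year.

    Each year keeps the previous use with probability ``persistence``
    and otherwise redraws from the mix, so the stationary distribution
    is the configured mix itself.
    """
    if years < 1:
        raise ConfigurationError("years must be >= 1")
    uses = [u for u, p in land_use_mix.items() if p > 0]
    probs = np.array([land_use_mix[u] for u in uses], dtype=float)
    if len(uses) == 0 or probs.sum() <= 0:
        raise ConfigurationError("degenerate land-use mix")
    probs = probs / probs.sum()
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    seq = [uses[rng.choice(len(uses), p=probs)]]
    for _ in range(years - 1):
        if rng.uniform() < persistence:
            seq.append(seq[-1])
        else:
            seq.append(uses[rng.choice(len(uses), p=probs)])
    return seq


def _draw_choice(rng: np.random.Generator, items, probs) -> Any:
    probs = np.asarray(probs, dtype=float)
    return items[rng.choice(len(items), p=probs / probs.sum())]


#: Observer noise (sd on the 0-1 rating latent) of a visual assessment.
VSA_OBSERVER_SD = 0.08


def _vsa_from_state(
    rng: np.random.Generator,
    q: float,
    base: Mapping[str, float],
    models: Mapping[str, TruncNormSpec],
    gw: GroundwaterClass,
) -> VSARecord:
    """Visual assessment of the simulated soil state.

    Each item's rating latent is driven by the properties a field
    observer would actually be seeing — bulk density for compaction and
    rooting, organic matter and soil life for structure and biota,
    groundwater depth for wetness signs — plus the latent field quality
    and modest observer noise, then discretized to poor/moderate/good.
    """

    def goodness(name: str, hi_good: bool = True) -> float:
        spec = models[name]
        s = (base[name] - spec.lo) / (spec.hi - spec.lo)
        return s if hi_good else 1.0 - s

    s_phys = goodness("bulk_density", hi_good=False)
    s_bio = 0.5 * goodness("organic_matter") + 0.5 * goodness("pmn")
    s_drain = gw.depth_rank / (len(GroundwaterClass) - 1)  # deep = dry
    signal = {
        "earthworms": s_bio,
        "compaction": s_phys,
        "gray_spots": s_drain,
        "ponding": 0.7 * s_drain + 0.3 * s_phys,
        "cracks": 0.5 * s_phys + 0.5 * s_bio,
        "bio_pores": s_bio,
        "rooting_depth": 0.7 * s_phys + 0.3 * s_drain,
        "structure": 0.5 * s_phys + 0.5 * s_bio,
        "crop_cover": 0.5,
    }
    ratings = {}
    for item in VSA_ITEMS:
        z = 0.15 + 0.7 * signal[item] + 0.12 * q + rng.normal(0.0, VSA_OBSERVER_SD)
        if z < 1 / 3:
            ratings[item] = VSARating.POOR
        elif z < 2 / 3:
            ratings[item] = VSARating.MODERATE
        else:
            ratings[item] = VSARating.GOOD
    return VSARecord(**ratings)


def _field_base_properties(
    rng: np.random.Generator,
    models: Mapping[str, TruncNormSpec],
    q: float,
) -> dict[str, float]:
    base: dict[str, float] = {}
    for name, spec in models.items():
        load = QUALITY_LOADINGS.get(name, 0.0)
        mu = spec.mean + load * q * spec.sd
        base[name] = _truncnorm(rng, spec, mean=mu, sd=spec.sd * 0.9)
    return base


def _records_for_field(
    field_id: str,
    rng: np.random.Generator,
    cfg: SimulationConfig,
    soil_type: SoilType,
    gw: GroundwaterClass,
    rotation: list[LandUse],
    base: dict[str, float],
    q: float,
    with_vsa: bool,
) -> list[FieldYearRecord]:
    models = cfg.property_models[soil_type]
    mgmt = ManagementRecord(
        score=float(np.clip(rng.normal(0.65 + 0.1 * q, 0.08), 0.0, 1.0))
    )
    vsa = _vsa_from_state(rng, q, base, models, gw) if with_vsa else None
    texture_names = ("clay", "silt")
    records = []
    for age in range(cfg.years):
        props: dict[str, float] = {}
        for name, b in base.items():
            if name in texture_names:
                props[name] = b  # texture is stable across years
            else:
                spec = models[name]
                jitter = rng.normal(0.0, cfg.year_jitter * spec.sd)
                props[name] = float(np.clip(b + jitter, spec.lo, spec.hi))
        clay, silt = props["clay"], props["silt"]
        if clay + silt > 99.0:  # keep a physical texture triplet
            scale = 99.0 / (clay + silt)
            clay, silt = clay * scale, silt * scale
        props["clay"], props["silt"] = clay, silt
        props["sand"] = 100.0 - clay - silt
        land_use = rotation[age]
        crop = {
            LandUse.GRASSLAND: "grass",
            LandUse.MAIZE: "silage_maize",
        }.get(land_use) or _ARABLE_CROPS[rng.choice(len(_ARABLE_CROPS))]
        records.append(
            FieldYearRecord(
                field_id=field_id,
                year_age=age,
                profile=SoilProfile(**props),
                context=FieldContext(
                    soil_type=soil_type,
                    groundwater_class=gw,
                    land_use=land_use,
                    crop_code=crop,
                ),
                management=mgmt,
                vsa=vsa,
            )
        )
    return records


def generate_fields(cfg: SimulationConfig | None = None) -> list[FieldYearRecord]:
    """Generate ``cfg.n_fields`` fields x ``cfg.years`` validated records."""
    cfg = cfg or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    soil_types = list(cfg.soil_type_mix)
    st_probs = [cfg.soil_type_mix[s] for s in soil_types]
    out: list[FieldYearRecord] = []
    for i in range(cfg.n_fields):
        st = _draw_choice(rng, soil_types, st_probs)
        gw_items = DEFAULT_GROUNDWATER[st]
        gw = _draw_choice(rng, [g for g, _ in gw_items], [p for _, p in gw_items])
        rotation = generate_rotation(
            cfg.years, cfg.land_use_mix[st], rng, cfg.persistence
        )
        q = rng.normal(0.0, cfg.quality_sd)
        base = _field_base_properties(rng, cfg.property_models[st], q)
        with_vsa = rng.uniform() < cfg.vsa_fraction
        recs = _records_for_field(
            f"field_{i:05d}", rng, cfg, st, gw, rotation, base, q, with_vsa
        )
        for r in recs:
            r.validate()
        out.extend(recs)
    return out


def generate_pairs(
    n_pairs: int,
    pair_offset: float | None = None,
    seed: int = 0,
    cfg: SimulationConfig | None = None,
) -> list[tuple[list[FieldYearRecord], list[FieldYearRecord]]]:
    """Generate good/poor field pairs sharing soil type, hydrology and
    rotation; both members carry a complete VSA.

    The poor member's deficiency-linked properties (organic matter,
    potentially mineralizable N, bulk density) are moved ``pair_offset``
    of the way from the good member's value toward the deficient
    truncation bound; its VSA latent quality is shifted down
    accordingly. ``pair_offset=0`` makes the members statistically
    exchangeable (independent year noise only).
    """
    if n_pairs < 1:
        raise ConfigurationError("n_pairs must be >= 1")
    cfg = cfg or SimulationConfig()
    if pair_offset is not None:
        cfg = replace(cfg, pair_offset=pair_offset)
    cfg.validate()
    rng = np.random.default_rng(seed)
    soil_types = list(cfg.soil_type_mix)
    st_probs = [cfg.soil_type_mix[s] for s in soil_types]
    pairs = []
    for i in range(n_pairs):
        st = _draw_choice(rng, soil_types, st_probs)
        gw_items = DEFAULT_GROUNDWATER[st]
        gw = _draw_choice(rng, [g for g, _ in gw_items], [p for _, p in gw_items])
        rotation = generate_rotation(
            cfg.years, cfg.land_use_mix[st], rng, cfg.persistence
        )
        q = rng.normal(0.0, cfg.quality_sd)
        models = cfg.property_models[st]
        base_good = _field_base_properties(rng, models, q)
        base_poor = dict(base_good)
        for name, side in PAIR_DEFICIENCY_SIDE.items():
            spec = models[name]
            bound = spec.lo if side == "lo" else spec.hi
            base_poor[name] = base_good[name] + cfg.pair_offset * (
                bound - base_good[name]
            )
        q_poor = q - 2.0 * cfg.pair_offset
        good = _records_for_field(
            f"pair{i:02d}_good", rng, cfg, st, gw, rotation, base_good, q, True
        )
        poor = _records_for_field(
            f"pair{i:02d}_poor", rng, cfg, st, gw, rotation, base_poor, q_poor, True
        )
        for r in good + poor:
            r.validate()
        pairs.append((good, poor))
    return pairs
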