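import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import soilscore as ss

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def battery() -> ss.Battery:
    return ss.default_battery()


@pytest.fixture(scope="session")
def practices() -> ss.PracticeSet:
    return ss.default_practices()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_record(
    field_id: str = "f1",
    year_age: int = 0,
    soil_type: ss.SoilType = ss.SoilType.SAND,
    land_use: ss.LandUse = ss.LandUse.ARABLE,
    gw: ss.GroundwaterClass = ss.GroundwaterClass.IV,
    management: float | None = 0.7,
    vsa: ss.VSARecord | None = None,
    **profile_overrides,
) -> ss.FieldYearRecord:
    """A complete, valid sandy arable field-year; override as needed."""
    profile = dict(
        organic_matter=4.5, ph=5.6, clay=4.0, silt=12.0, sand=84.0,
        n_total=1500.0, p_avail=45.0, k_avail=120.0, mg_avail=85.0,
        cu_avail=3.0, s_avail=15.0, zn_avail=5.0, cec=80.0,
        pmn=60.0, bulk_density=1.45,
    )
    profile.update(profile_overrides)
    rec = ss.FieldYearRecord(
        field_id=field_id,
        year_age=year_age,
        profile=ss.SoilProfile(**profile),
        context=ss.FieldContext(
            soil_type=soil_type, groundwater_class=gw, land_use=land_use,
            crop_code="potato",
        ),
        management=(
            ss.ManagementRecord(score=management) if management is not None else None
        ),
        vsa=vsa,
    )
    rec.validate()
    return rec


def make_vsa(default: str = "good", **overrides) -> ss.VSARecord:
    from soilscore.types import VSA_ITEMS

    ratings = {item: ss.VSARating(overrides.get(item, default)) for item in VSA_ITEMS}
    return ss.VSARecord(**ratings)


@pytest.fixture()
def complete_record() -> ss.FieldYearRecord:
    return make_record()
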