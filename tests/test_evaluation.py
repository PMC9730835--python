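"""Battery loading, indicator evaluation, score classification."""

import random

import pytest
import yaml

import soilscore as ss
from soilscore import ConfigurationError, InputError
from soilscore.evaluation import Battery, IndicatorSource, evaluate_indicator
from soilscore.types import Category

from conftest import make_record


class TestDefaultBattery:
    def test_has_22_functions_with_minimum_coverage(self, battery):
        assert len(battery) == 22
        counts = {
            cat: sum(1 for d in battery if d.category is cat) for cat in Category
        }
        assert counts[Category.CHEMICAL] == 9
        assert counts[Category.PHYSICAL] == 8
        assert counts[Category.BIOLOGICAL] == 2
        assert counts[Category.ENVIRONMENTAL] == 2
        assert counts[Category.MANAGEMENT] == 1

    def test_coverage_rule_rejected_at_load(self, battery):
        defs = [d for d in battery if d.category is not Category.BIOLOGICAL]
        with pytest.raises(ConfigurationError, match="biological"):
            Battery(defs)

    def test_duplicate_function_id_rejected(self, battery):
        defs = list(battery.definitions) + [battery["i_c_n"]]
        with pytest.raises(ConfigurationError, match="duplicate"):
            Battery(defs)


class TestClassification:
    @pytest.mark.parametrize(
        "score, expected",
        [
            (0.76, "good"),
            (0.75, "sufficient"),
            (0.5, "sufficient"),
            (0.49, "poor"),
            (1.0, "good"),
            (0.0, "poor"),
        ],
    )
    def test_printed_thresholds(self, score, expected):
        assert ss.classify_score(score).value == expected

    @pytest.mark.parametrize("bad", [-0.01, 1.01, float("nan")])
    def test_out_of_domain_rejected(self, bad):
        with pytest.raises(InputError):
            ss.classify_score(bad)


class TestEvaluateIndicator:
    def test_value_at_optimum_anchor_is_one(self, battery):
        # sand/arable nitrogen curve has x_opt = 2500
        rec = make_record(n_total=2500.0)
        iv = evaluate_indicator(battery["i_c_n"], rec)
        assert iv.value == 1.0
        assert iv.source is IndicatorSource.MEASURED_CURVE

    def test_missing_property_gives_missing_not_zero(self, battery):
        rec = make_record(pmn=None)
        iv = evaluate_indicator(battery["i_b_pmn"], rec)
        assert iv.value is None

    def test_equals_direct_curve_primitive(self, battery, complete_record):
        """Oracle: each indicator equals its curve applied by hand to the
        extracted property."""
        rec = complete_record
        for defn in battery:
            curve = defn.curve_for(rec.context.soil_type, rec.context.land_use)
            prop = defn.required_properties[0]
            if prop == "groundwater_class":
                raw = rec.context.groundwater_class.value
            elif prop == "management_score":
                raw = rec.management.score
            else:
                raw = getattr(rec.profile, prop)
            expected = curve.evaluate(raw, defn.function_id)
            assert evaluate_indicator(defn, rec).value == expected

    def test_stratum_resolution_prefers_specific_curve(self, battery):
        # peat has its own nitrogen curve (x_zero=0, x_half=3000): the
        # generic sand value 1500 scores 0.25 on it, not 0.67
        rec = make_record(soil_type=ss.SoilType.PEAT, ph=5.0, n_total=1500.0)
        iv = evaluate_indicator(battery["i_c_n"], rec)
        assert iv.value == pytest.approx(0.25)


class TestEvaluateBattery:
    def test_complete_record_evaluates_everything(self, battery, complete_record):
        vec = ss.evaluate_battery(battery, complete_record)
        present = [iv for iv in vec.values() if iv.value is not None]
        assert len(vec) == 22
        assert len(present) == 22  # 21 measured + management from config
        mgmt = vec["i_m_management"]
        assert mgmt.source is IndicatorSource.CONFIG
        assert mgmt.value == pytest.approx(0.7)

    def test_missing_biological_assays_stay_local(self, battery):
        full = ss.evaluate_battery(battery, make_record())
        vec = ss.evaluate_battery(battery, make_record(pmn=None))
        assert vec["i_b_pmn"].value is None
        for fid, iv in vec.items():
            if fid != "i_b_pmn":
                assert iv.value == full[fid].value

    def test_downsized_profile_evaluates_only_supported_functions(self, battery):
        """A routine 10-parameter profile (total N, available P/K, CEC,
        pH, texture, organic C, bulk density) covers a subset of the
        battery; the rest is missing, never zero."""
        rec = make_record(
            mg_avail=None, cu_avail=None, s_avail=None, zn_avail=None,
            pmn=None, management=None,
        )
        vec = ss.evaluate_battery(battery, rec)
        missing = {fid for fid, iv in vec.items() if iv.value is None}
        assert missing == {
            "i_c_mg", "i_c_cu", "i_c_s", "i_c_zn", "i_b_pmn", "i_m_management"
        }

    def test_output_independent_of_definition_order(self, battery, complete_record):
        shuffled = list(battery.definitions)
        random.Random(7).shuffle(shuffled)
        vec_a = ss.evaluate_battery(battery, complete_record)
        vec_b = ss.evaluate_battery(Battery(shuffled), complete_record)
        assert {f: iv.value for f, iv in vec_a.items()} == {
            f: iv.value for f, iv in vec_b.items()
        }


class TestBatteryLoading:
    def _minimal_config(self):
        curve = {"kind": "two_anchor_increasing", "x_half": 1, "x_opt": 2}
        mk = lambda fid, cat, prop: {
            "function_id": fid, "category": cat,
            "required_properties": [prop], "curves": {"*:*": dict(curve)},
        }
        return {
            "battery": [
                mk("c1", "chemical", "n_total"), mk("c2", "chemical", "p_avail"),
                mk("p1", "physical", "clay"), mk("p2", "physical", "silt"),
                mk("b1", "biological", "pmn"), mk("b2", "biological", "organic_matter"),
            ]
        }

    def test_loads_from_yaml_file(self, tmp_path):
        path = tmp_path / "battery.yaml"
        path.write_text(yaml.safe_dump(self._minimal_config()))
        battery = ss.load_battery(path)
        assert len(battery) == 6

    def test_error_names_the_offending_entry(self, tmp_path):
        cfg = self._minimal_config()
        del cfg["battery"][3]["curves"]
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump(cfg))
        with pytest.raises(ConfigurationError, match=r"battery\[3\]"):
            ss.load_battery(path)

    def test_missing_stratum_curve_names_stratum(self):
        cfg = self._minimal_config()
        for entry in cfg["battery"]:
            entry["curves"] = {"sand:arable": entry["curves"]["*:*"]}
        battery = ss.load_battery(cfg)
        rec = make_record(soil_type=ss.SoilType.CLAY, ph=6.5)
        with pytest.raises(ConfigurationError, match="clay x arable"):
            evaluate_indicator(battery["c1"], rec)

    def test_unknown_property_rejected(self):
        cfg = self._minimal_config()
        cfg["battery"][0]["required_properties"] = ["unobtainium"]
        with pytest.raises(ConfigurationError, match="unobtainium"):
            ss.load_battery(cfg)
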