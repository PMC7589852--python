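"""Instance data model, validation and serialization."""

import pytest

from ipftsp.instance import (
    instance_from_json,
    instance_to_json,
    intake_group,
    load_csv_bundle,
    validate_instance,
)
class TestValidation:
    def test_case_study_skeleton_is_clean(self, mnnr):
        inst, _ = mnnr
        assert validate_instance(inst) == []

    def test_validation_is_idempotent(self, small_instance):
        assert validate_instance(small_instance) == validate_instance(small_instance)

    def test_bad_probability_sum_is_reported(self, small_instance):
        bad = small_instance.model_copy(deep=True)
        bad.scenarios[0].probability = 0.5
        bad.scenarios[1].probability = 0.6
        assert any("probabilities sum" in v for v in validate_instance(bad))

    def test_dangling_intake_reference_is_reported(self, small_instance):
        bad = small_instance.model_copy(deep=True)
        bad.lakes[0].intake_id = 99
        msgs = validate_instance(bad)
        assert any("unknown intake 99" in v for v in msgs)

    def test_area_bound_ordering_is_reported(self, small_instance):
        from ipftsp.fuzzy import FuzzyBound

        bad = small_instance.model_copy(deep=True)
        top = bad.lakes[0].regions[0].area_max.a
        bad.lakes[0].regions[0].area_min = FuzzyBound(top + 1.0, top + 2.0)
        assert any("minimum area bound exceeds" in v for v in validate_instance(bad))


class TestIntakeGroups:
    def test_case_study_grouping(self, mnnr):
        inst, _ = mnnr
        assert intake_group(inst, 1) == list(range(1, 10))
        assert intake_group(inst, 2) == [10, 11, 12]
        assert intake_group(inst, 3) == [13, 14, 15, 16]
        assert intake_group(inst, 4) == [17, 18]

    def test_groups_partition_the_lakes(self, default_instance):
        seen = []
        for n in default_instance.intakes:
            seen.extend(intake_group(default_instance, n))
        assert sorted(seen) == default_instance.lake_ids

    def test_unknown_intake_errors(self, small_instance):
        with pytest.raises(KeyError):
            intake_group(small_instance, 42)


class TestSerialization:
    def test_json_roundtrip_is_byte_identical(self, default_instance):
        text = instance_to_json(default_instance)
        assert instance_to_json(instance_from_json(text)) == text

    def test_intervals_serialize_as_pairs(self, small_instance):
        import json

        doc = json.loads(instance_to_json(small_instance))
        lake = doc["lakes"][0]
        assert isinstance(lake["habitat_coefficient"], list)
        assert len(lake["habitat_coefficient"]) == 2
        region = lake["regions"][0]
        assert set(region["area_min"]) == {"b", "a"}

    def test_csv_bundle_maps_to_same_model(self, tmp_path, small_instance):
        import json

        import pandas as pd

        inst = small_instance
        lakes_rows, region_rows = [], []
        for lake in inst.lakes:
            lakes_rows.append(
                {
                    "lake_id": lake.lake_id,
                    "intake_id": lake.intake_id,
                    "C_lower": lake.habitat_coefficient.lower,
                    "C_upper": lake.habitat_coefficient.upper,
                    "QL_lower": lake.supply_loss.lower,
                    "QL_upper": lake.supply_loss.upper,
                    "QI_lower": lake.local_supply_cap.lower,
                    "QI_upper": lake.local_supply_cap.upper,
                    "QN_lower": lake.normal_supply_cap.lower,
                    "QN_upper": lake.normal_supply_cap.upper,
                    "TFA_b": lake.total_planning_area.b,
                    "TFA_a": lake.total_planning_area.a,
                    "TCS_lower": lake.carbon_sink_floor.lower,
                    "TCS_upper": lake.carbon_sink_floor.upper,
                }
            )
            for r in lake.regions:
                region_rows.append(
                    {
                        "lake_id": lake.lake_id,
                        "region_id": r.region_id,
                        "QR_lower": r.water_demand_per_area.lower,
                        "QR_upper": r.water_demand_per_area.upper,
                        "Amin_b": r.area_min.b,
                        "Amin_a": r.area_min.a,
                        "Amax_b": r.area_max.b,
                        "Amax_a": r.area_max.a,
                        "Y": r.exists,
                        "NCSA_lower": r.carbon_sink_per_area.lower,
                        "NCSA_upper": r.carbon_sink_per_area.upper,
                    }
                )
        scen_rows = [
            {
                "scenario_id": s.scenario_id,
                "probability": s.probability,
                "intake_id": n,
                "QTF_lower": v.lower,
                "QTF_upper": v.upper,
            }
            for s in inst.scenarios
            for n, v in s.flood_available.items()
        ]
        esv_rows = [
            {
                "region_id": j,
                "service_id": k,
                "ESV_lower": v.lower,
                "ESV_upper": v.upper,
                "TEB_lower": inst.system.esv_floor[k].lower,
                "TEB_upper": inst.system.esv_floor[k].upper,
            }
            for j, per_k in inst.system.esv_per_area.items()
            for k, v in per_k.items()
        ]
        pd.DataFrame(lakes_rows).to_csv(tmp_path / "lakes.csv", index=False)
        pd.DataFrame(region_rows).to_csv(tmp_path / "regions.csv", index=False)
        pd.DataFrame(scen_rows).to_csv(tmp_path / "scenarios.csv", index=False)
        pd.DataFrame(esv_rows).to_csv(tmp_path / "esv.csv", index=False)
        (tmp_path / "system.json").write_text(
            json.dumps(
                {
                    "habitat_target": [
                        inst.system.habitat_target.lower,
                        inst.system.habitat_target.upper,
                    ],
                    "bird_density": inst.system.bird_density,
                }
            )
        )

        approx = lambda v: pytest.approx(v, rel=1e-9)
        loaded = load_csv_bundle(tmp_path)
        assert validate_instance(loaded) == []
        assert loaded.lake_ids == inst.lake_ids
        for a, b in zip(loaded.lakes, inst.lakes):
            assert a.habitat_coefficient.lower == approx(b.habitat_coefficient.lower)
            assert a.habitat_coefficient.upper == approx(b.habitat_coefficient.upper)
            assert a.total_planning_area.b == approx(b.total_planning_area.b)
            for ra, rb in zip(a.regions, b.regions):
                assert ra.water_demand_per_area.lower == approx(
                    rb.water_demand_per_area.lower
                )
                assert ra.area_min.a == approx(rb.area_min.a)
        assert loaded.system.habitat_target == inst.system.habitat_target
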