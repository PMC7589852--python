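"""Sub-model construction: realizations, constraint families, big-M blocks."""

import numpy as np
import pytest

from ipftsp.builder import (
    big_m_value,
    build_submodel,
    realize_parameters,
)
from ipftsp.synthetic import generate

from conftest import small_config


class TestRealization:
    def test_adverse_run_takes_adverse_endpoints(self, small_instance):
        real = realize_parameters(small_instance, "lower_run")
        lake = small_instance.lakes[0]
        region = lake.regions[0]
        # the conservative run assumes each hectare demands the most water
        assert real.QR[lake.lake_id, region.region_id] == region.water_demand_per_area.upper
        assert real.C[lake.lake_id] == lake.habitat_coefficient.lower
        assert real.QI[lake.lake_id] == lake.local_supply_cap.lower
        assert real.TEB[1] == small_instance.system.esv_floor[1].upper

    def test_favorable_run_mirrors(self, small_instance):
        real = realize_parameters(small_instance, "upper_run")
        lake = small_instance.lakes[0]
        region = lake.regions[0]
        assert real.QR[lake.lake_id, region.region_id] == region.water_demand_per_area.lower
        assert real.C[lake.lake_id] == lake.habitat_coefficient.upper

    def test_override_flips_both_runs_consistently(self, small_instance):
        up = realize_parameters(small_instance, "upper_run", overrides={"C": "lower"})
        lo = realize_parameters(small_instance, "lower_run", overrides={"C": "lower"})
        lake = small_instance.lakes[0]
        assert up.C[lake.lake_id] == lake.habitat_coefficient.lower
        assert lo.C[lake.lake_id] == lake.habitat_coefficient.upper

    def test_unknown_override_family_rejected(self, small_instance):
        with pytest.raises(KeyError):
            realize_parameters(small_instance, "upper_run", overrides={"XX": "lower"})

    def test_crisp_instance_realizations_coincide(self):
        cfg = small_config(
            seed=5, qr_halfwidth=0, c_halfwidth=0, supply_halfwidth=0,
            qtf_halfwidth=0, ql_halfwidth=0, esv_halfwidth=0, ncsa_halfwidth=0,
            floor_halfwidth=0,
        )
        inst = generate(cfg)
        up = realize_parameters(inst, "upper_run")
        lo = realize_parameters(inst, "lower_run")
        for attr in ("C", "QR", "QL", "QI", "QN", "QTF", "ESV", "TEB", "NCSA", "TCS"):
            assert getattr(up, attr) == getattr(lo, attr)


class TestModelStructure:
    def test_constraint_family_counts_follow_index_sets(self, default_instance):
        # 18 lakes x 3 scenarios for the per-lake families, 4 intakes x 3
        # scenarios for the flood balances, one habitat target row
        sub = build_submodel(
            default_instance, realize_parameters(default_instance, "upper_run")
        )
        counts = sub.family_counts()
        assert counts["habitat_target"] == 1
        for family in (
            "min_demand", "supply_balance", "area_vs_habitat",
            "water_area_balance", "carbon_floor",
        ):
            assert counts[family] == 18 * 3
        assert counts["flood_cap"] == 4 * 3
        assert counts["area_max"] == 18 * 4 * 3
        assert counts["esv_floor"] == 3 * 3
        # each (lake, scenario) priority block: 5 pond rows + 3 reed rows
        assert counts["priority_ponds"] == 5 * 18 * 3
        assert counts["priority_reed"] == 3 * 18 * 3

    def test_lambda_enters_fuzzified_rows_linearly(self, small_instance):
        sub = build_submodel(
            small_instance, realize_parameters(small_instance, "upper_run")
        )
        by_name = {c.name: c for c in sub.model.constraints}
        lake = small_instance.lakes[0]
        h = small_instance.scenarios[0].scenario_id
        row = by_name[f"min_demand[{lake.lake_id},{h}]"]
        slope = sum(
            r.water_demand_per_area.lower * r.area_min.spread for r in lake.regions
        )
        assert row.coeffs[sub.lam] == pytest.approx(-slope)
        area_row = by_name[f"area_total[{lake.lake_id},{h}]"]
        assert area_row.coeffs[sub.lam] == pytest.approx(
            lake.total_planning_area.spread
        )

    def test_fixed_targets_pin_first_stage_bounds(self, small_instance):
        fixed = {lake.lake_id: 123.0 for lake in small_instance.lakes}
        sub = build_submodel(
            small_instance,
            realize_parameters(small_instance, "upper_run"),
            fixed_QT=fixed,
        )
        for i, idx in sub.QT.items():
            assert sub.model.lb[idx] == sub.model.ub[idx] == 123.0


class TestBigM:
    def test_big_m_certifies_expressions(self, small_instance):
        # M must dominate the largest water turnover a lake can see
        for lake in small_instance.lakes:
            m = big_m_value(small_instance, lake.lake_id)
            assert m >= lake.local_supply_cap.upper + lake.normal_supply_cap.upper
            qr_up = max(r.water_demand_per_area.upper for r in lake.regions)
            assert m >= qr_up * lake.total_planning_area.a

    def test_else_branch_forbids_wetland_water(self, small_instance, small_solution):
        # at a solved point, flipping an indicator to 0 while reed/marsh
        # still receive water must violate the pond else-branch row
        sub = build_submodel(
            small_instance,
            realize_parameters(small_instance, "upper_run"),
            fixed_QT=small_solution.upper.QT,
        )
        x = np.zeros(sub.model.n_vars)
        sol = small_solution.upper
        x[sub.lam] = sol.lam_opt
        for store, vmap in (
            (sol.QT, sub.QT), (sol.QS, sub.QS), (sol.QID, sub.QID),
            (sol.QND, sub.QND), (sol.QFD, sub.QFD), (sol.FA, sub.FA),
            (sol.d1, sub.d1), (sol.d2, sub.d2),
        ):
            for key, j in vmap.items():
                x[j] = store[key]
        assert sub.model.residuals(x).get("priority_ponds", 0.0) <= 1e-9

        key = next(iter(sub.d1))
        assert sol.d1[key] == 1  # ponds reach their minimum at the optimum
        x[sub.d1[key]] = 0.0
        res = sub.model.residuals(x)
        assert res["priority_ponds"] > 1e-3

    def test_lp_export_contains_model_sections(self, small_instance):
        sub = build_submodel(
            small_instance, realize_parameters(small_instance, "upper_run")
        )
        text = sub.model.to_lp_string()
        assert text.startswith("Maximize")
        for section in ("Subject To", "Bounds", "Binaries", "End"):
            assert section in text
        assert "lam" in text and "QT(1)" in text
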