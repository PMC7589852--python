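"""Two-step solve driver, brute-force oracle and solution verification."""

import pytest

from ipftsp.fuzzy import FuzzyBound, IntervalValue
from ipftsp.instance import (
    FunctionRegionSpec,
    LakeSpec,
    ProblemInstance,
    ScenarioSpec,
    SystemSpec,
    validate_instance,
)
from ipftsp.solve import (
    InfeasibleSubmodelError,
    bisection_oracle,
    solve_ipftsp,
    solve_submodel,
    verify_solution,
)
from ipftsp.synthetic import generate

from conftest import small_config


def single_region_toy(local_cap: float) -> ProblemInstance:
    """One lake, one scenario, one region: the membership optimum has the
    closed form clip((cap/QR - Amin.b) / Amin.spread, 0, 1), because the
    only fuzzified row that can bind is the minimum-area requirement."""
    region = FunctionRegionSpec(
        region_id=1,
        water_demand_per_area=IntervalValue.crisp(1000.0),
        area_min=FuzzyBound(0.4, 0.6),
        area_max=FuzzyBound(1.0, 1.2),
        carbon_sink_per_area=IntervalValue.crisp(0.0),
    )
    lake = LakeSpec(
        lake_id=1,
        intake_id=1,
        habitat_coefficient=IntervalValue.crisp(1e-3),
        local_supply_cap=IntervalValue.crisp(local_cap),
        normal_supply_cap=IntervalValue.crisp(0.0),
        total_planning_area=FuzzyBound(1.5, 2.0),
        regions=[region],
    )
    return ProblemInstance(
        system=SystemSpec(habitat_target=IntervalValue(0.1e-3 * 1000, 0.2e-3 * 1000)),
        intakes={1: "gate"},
        lakes=[lake],
        scenarios=[
            ScenarioSpec(
                scenario_id=1, probability=1.0,
                flood_available={1: IntervalValue.crisp(0.0)},
            )
        ],
    )


class TestClosedFormToys:
    @pytest.mark.parametrize(
        "cap,expected_lam",
        [
            (1000.0, 1.0),  # ample supply: every fuzzy requirement at full
            (400.0, 0.0),  # supply covers only the fully relaxed minimum
            (500.0, 0.5),  # interior threshold (500/1000 - 0.4) / 0.2
            (460.0, 0.3),
        ],
    )
    def test_membership_threshold(self, cap, expected_lam):
        inst = single_region_toy(cap)
        assert validate_instance(inst) == []
        sol = solve_ipftsp(inst)
        assert sol.lam.lower == pytest.approx(expected_lam, abs=1e-7)
        assert sol.lam.upper == pytest.approx(expected_lam, abs=1e-7)

    @pytest.mark.parametrize("cap,expected_lam", [(1000.0, 1.0), (400.0, 0.0), (500.0, 0.5)])
    def test_oracle_matches_closed_form(self, cap, expected_lam):
        inst = single_region_toy(cap)
        lam = bisection_oracle(inst, "upper_run", grid_tol=5e-5)
        assert lam == pytest.approx(expected_lam, abs=1e-4)


class TestTwoStepDriver:
    def test_lower_run_is_a_tightening(self, small_solution):
        assert small_solution.lower.lam_opt <= small_solution.upper.lam_opt + 1e-9

    def test_net_supplement_intervals_are_paired(self, small_solution):
        for key, v in small_solution.Q.items():
            lo = small_solution.lower.net_supplement(*key)
            up = small_solution.upper.net_supplement(*key)
            assert v.lower == pytest.approx(min(lo, up))
            assert v.upper == pytest.approx(max(lo, up))

    def test_first_stage_consistency(self, small_instance, small_solution):
        # re-solving the favorable run with its own targets pinned must
        # reproduce the same membership optimum
        again = solve_submodel(
            small_instance, "upper_run", fixed_QT=small_solution.upper.QT
        )
        assert again.lam_opt == pytest.approx(
            small_solution.upper.lam_opt, abs=1e-7
        )

    def test_repeat_solve_is_bit_identical(self, small_instance):
        a = solve_ipftsp(small_instance)
        b = solve_ipftsp(small_instance)
        assert a.lam == b.lam
        assert a.upper.QT == b.upper.QT
        assert a.lower.QS == b.lower.QS
        assert a.upper.FA == b.upper.FA

    def test_flood_scaling_never_decreases_membership(self, small_instance):
        base = solve_ipftsp(small_instance)
        for c in (1.3, 2.0):
            scaled = small_instance.model_copy(deep=True)
            for s in scaled.scenarios:
                s.flood_available = {
                    n: IntervalValue(v.lower * c, v.upper * c)
                    for n, v in s.flood_available.items()
                }
            more = solve_ipftsp(scaled)
            assert more.lam.upper >= base.lam.upper - 1e-7
            assert more.lam.lower >= base.lam.lower - 1e-7

    def test_infeasible_benefit_floor_is_diagnosed(self, small_instance):
        bad = small_instance.model_copy(deep=True)
        bad.system.esv_floor = {
            k: IntervalValue(v.lower * 100, v.upper * 100)
            for k, v in bad.system.esv_floor.items()
        }
        with pytest.raises(InfeasibleSubmodelError) as exc:
            solve_ipftsp(bad)
        assert "esv_floor" in exc.value.diagnosis


class TestVerification:
    def test_solver_output_verifies(self, small_instance, small_solution):
        report = verify_solution(small_instance, small_solution, tol=1e-6)
        assert report.passed, report.violations()

    def test_corrupted_shortage_is_flagged(self, small_instance, small_solution):
        import copy

        corrupted = copy.deepcopy(small_solution)
        key = next(iter(corrupted.lower.QS))
        corrupted.lower.QS[key] += 1.0
        report = verify_solution(small_instance, corrupted, tol=1e-6)
        assert not report.passed
        assert "water_area_balance" in report.violations()["lower_run"]

    def test_inflated_membership_is_flagged(self, small_instance, small_solution):
        import copy

        corrupted = copy.deepcopy(small_solution)
        corrupted.upper.lam_opt = min(1.0, corrupted.upper.lam_opt + 0.1)
        report = verify_solution(small_instance, corrupted, tol=1e-6)
        assert not report.passed
        flagged = report.violations()["upper_run"]
        # a higher membership tightens the fuzzified requirement rows
        assert any(
            fam in flagged
            for fam in ("habitat_target", "min_demand", "priority_ponds", "area_total")
        )


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", [11, 12])
    def test_milp_equals_enumeration(self, seed):
        inst = generate(small_config(seed=seed))
        sol = solve_ipftsp(inst)
        up = bisection_oracle(inst, "upper_run", grid_tol=5e-5)
        lo = bisection_oracle(
            inst, "lower_run", grid_tol=5e-5, fixed_QT=sol.upper.QT
        )
        assert abs(sol.upper.lam_opt - up) <= 1e-4
        assert abs(sol.lower.lam_opt - lo) <= 1e-4

    def test_oracle_refuses_large_instances(self, default_instance):
        with pytest.raises(ValueError):
            bisection_oracle(default_instance, "upper_run")
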