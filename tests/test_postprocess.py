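"""Derived reporting: accounting identities, capacities, comparisons."""

import pytest

from ipftsp.builder import realize_parameters
from ipftsp.fuzzy import IntervalValue, width_reduction_ratio
from ipftsp.postprocess import (
    as_percent,
    benefit_accounting,
    build_report,
    carrying_capacity,
    compare_schemes,
    fixture_supply_accounting,
    flood_share,
    habitat_area,
    round_half_up,
    water_shortage,
)
from ipftsp.synthetic import RunPair


class TestRounding:
    def test_half_up_matches_table_style(self):
        assert round_half_up(0.125) == 0.13
        assert round_half_up(0.124999) == 0.12
        assert as_percent(0.26017) == 26.02


class TestCarryingCapacity:
    @pytest.mark.parametrize(
        "area,expected",
        [(14.06, 18.50), (15.83, 20.83), (0.0, 0.0)],
    )
    def test_printed_capacities(self, area, expected):
        assert carrying_capacity(area, 0.76) == pytest.approx(expected, abs=0.005)

    def test_linearity(self):
        a, b, d = 3.7, 9.2, 0.76
        assert carrying_capacity(a + b, d) == pytest.approx(
            carrying_capacity(a, d) + carrying_capacity(b, d)
        )

    def test_positive_density_required(self):
        with pytest.raises(ValueError):
            carrying_capacity(1.0, 0.0)


class TestFixtureAccounting:
    def test_headline_supply_numbers(self, mnnr):
        _, fx = mnnr
        acc = fixture_supply_accounting(fx)
        assert acc.total_target == pytest.approx(24924.81, abs=0.011)
        assert acc.actual_total[1].lower == pytest.approx(18833.44, abs=0.011)
        assert acc.actual_total[3].upper == pytest.approx(24161.79, abs=0.011)
        assert as_percent(acc.flood_share[1].upper) == pytest.approx(29.05, abs=0.011)
        assert as_percent(acc.relative_range[2]) == pytest.approx(17.30, abs=0.011)
        assert as_percent(acc.width_reduction[3]) == pytest.approx(49.62, abs=0.011)

    def test_region_habitat_cells_sum_to_totals(self, mnnr):
        _, fx = mnnr
        for h in (1, 2, 3):
            lo = sum(fx.habitat_regions[r, h].lower_run for r in (1, 2, 3, 4))
            up = sum(fx.habitat_regions[r, h].upper_run for r in (1, 2, 3, 4))
            # printed cells carry up to 0.01 rounding drift per entry
            assert lo == pytest.approx(fx.habitat_total[h].lower_run, abs=0.05)
            assert up == pytest.approx(fx.habitat_total[h].upper_run, abs=0.05)


class TestSolutionAccounting:
    def test_shortage_plus_net_supply_equals_target(
        self, small_instance, small_solution
    ):
        for which in ("lower_run", "upper_run"):
            sol = small_solution.run(which)
            real = realize_parameters(small_instance, which)
            for (i, h), qs in sol.QS.items():
                actual = sol.QID[i, h] + sol.QND[i, h] + sol.QFD[i, h]
                assert qs + actual - real.QL[i] == pytest.approx(
                    sol.QT[i], abs=1e-6
                )

    def test_region_habitat_sums_to_total(self, default_instance, default_solution):
        region = habitat_area(default_solution, default_instance, "region")
        total = habitat_area(default_solution, default_instance, "total")
        for h in (1, 2, 3):
            lo = sum(v.lower for (n, hh), v in region.items() if hh == h)
            up = sum(v.upper for (n, hh), v in region.items() if hh == h)
            assert lo == pytest.approx(total[h].lower, abs=1e-9)
            assert up == pytest.approx(total[h].upper, abs=1e-9)

    def test_expected_target_is_a_probability_mixture(
        self, default_instance, default_solution
    ):
        total = habitat_area(default_solution, default_instance, "total")
        target = habitat_area(default_solution, default_instance, "expected_target")[
            "target"
        ]
        lo_min = min(v.lower for v in total.values())
        up_max = max(v.upper for v in total.values())
        assert lo_min - 1e-9 <= target.lower <= target.upper <= up_max + 1e-9

    def test_flood_share_is_a_fraction(self, default_solution):
        for v in flood_share(default_solution).values():
            assert 0.0 <= v.lower <= v.upper <= 1.0

    def test_shortage_totals_match_lake_sums(self, small_solution):
        lake = water_shortage(small_solution, "lake")
        total = water_shortage(small_solution, "total")
        scenarios = sorted({h for _, h in small_solution.upper.QS})
        for h in scenarios:
            lo = sum(
                small_solution.lower.QS[i, hh]
                for (i, hh) in small_solution.lower.QS
                if hh == h
            )
            up = sum(
                small_solution.upper.QS[i, hh]
                for (i, hh) in small_solution.upper.QS
                if hh == h
            )
            assert total[h].lower == pytest.approx(min(lo, up), abs=1e-9)
        assert set(lake) == {
            (i, h) for i, h in small_solution.upper.QS
        }

    def test_benefit_sums_match_direct_summation(
        self, small_instance, small_solution
    ):
        acc = benefit_accounting(small_solution, small_instance)
        assert acc.floor_violations == []
        real = realize_parameters(small_instance, "upper_run")
        h = 1
        by_hand = sum(
            small_solution.upper.FA[l.lake_id, r.region_id, h]
            * real.ESV[r.region_id, k]
            for l in small_instance.lakes
            for r in l.regions
            for k in small_instance.system.service_functions
        )
        total = acc.esv_total[h]
        assert by_hand == pytest.approx(max(total.lower, total.upper), rel=1e-9) or (
            by_hand == pytest.approx(min(total.lower, total.upper), rel=1e-9)
        )


class TestComparisons:
    def test_equal_value_means_zero_change(self):
        out = compare_schemes({1: RunPair(10.0, 10.0)}, 10.0)
        change = out["percent_change"][1]
        assert change.lower == change.upper == 0.0

    def test_habitat_width_reduction_identity(self):
        # recomputing on the printed inputs gives the exact ratio of widths
        new = IntervalValue(14.06, 17.88)
        ref = IntervalValue(13.99, 18.59)
        assert width_reduction_ratio(new, ref) == pytest.approx(
            1.0 - 3.82 / 4.60, abs=1e-12
        )

    def test_report_bundle_on_solved_instance(
        self, default_instance, default_solution, tmp_path
    ):
        from ipftsp.postprocess import report_markdown, write_report

        bundle = build_report(default_instance, default_solution)
        assert bundle.lam == default_solution.lam
        # per run, the region areas sum exactly to the grand total (pairing
        # happens only afterwards, so sorted endpoints may not be additive)
        region_ids = default_instance.region_ids
        for which in ("lower", "upper"):
            sol = getattr(default_solution, which)
            for h, v in bundle.total_area.items():
                run_total = sum(
                    sol.FA[i, j, h]
                    for i in default_instance.lake_ids
                    for j in region_ids
                )
                assert (
                    min(abs(run_total - v.lower), abs(run_total - v.upper)) <= 1e-9
                )
        # every reported interval is sorted by construction
        for v in list(bundle.habitat_total.values()) + list(
            bundle.supply.actual_total.values()
        ):
            assert v.lower <= v.upper
        write_report(bundle, tmp_path)
        assert (tmp_path / "supply_accounting.csv").exists()
        text = report_markdown(bundle)
        assert "fuzzy membership lambda" in text
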