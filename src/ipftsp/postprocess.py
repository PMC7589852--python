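"""Derived quantities of a solved plan: supply accounting, habitat areas,
bird carrying capacity, flood shares, benefit accounting and comparisons.

Everything here is pure arithmetic on solved sub-model runs (or on printed
result tables with the same shape).  Derived values are computed per run
at full precision, then combined into sorted intervals; percentages are
stored as fractions and formatted only at the reporting boundary, rounded
half-up to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

from .builder import realize_parameters
from .fuzzy import (
    IntervalValue,
    interval_relative_range,
    paired_interval,
    width_reduction_ratio,
)
from .instance import ProblemInstance, intake_group
from .solve import IpftspSolution, SubmodelSolution
from .synthetic import RunPair

__all__ = [
    "SupplyAccounting",
    "ReportBundle",
    "actual_supply",
    "water_shortage",
    "habitat_area",
    "carrying_capacity",
    "flood_share",
    "benefit_accounting",
    "compare_schemes",
    "supply_accounting",
    "build_report",
    "write_report",
    "report_markdown",
]

_RUNS = ("lower_run", "upper_run")


def _pair(pair: RunPair) -> IntervalValue:
    return paired_interval(pair.lower_run, pair.upper_run)


def round_half_up(x: float, digits: int = 2) -> float:
    """Round half away from zero to match the printed tables."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP)) + 0.0


def as_percent(fraction: float, digits: int = 2) -> float:
    return round_half_up(100.0 * fraction, digits)


# ---------------------------------------------------------------------------
# solution-level accounting
# ---------------------------------------------------------------------------


def _run_actual(sol: SubmodelSolution, i: int, h: int) -> float:
    return sol.QID[i, h] + sol.QND[i, h] + sol.QFD[i, h]


def actual_supply(
    solution: IpftspSolution, level: str = "total"
) -> Dict[object, IntervalValue]:
    """Actual water supply (local + normal + flood), paired across runs.

    ``level`` is ``"lake"`` (keys ``(i, h)``), ``"intake"`` (``(n, h)``,
    requires lake keys grouped via the solution's instance-free data: the
    intake is not stored per lake here, so intake level needs
    :func:`build_report`), or ``"total"`` (keys ``h``).
    """
    lakes = sorted({i for i, _ in solution.upper.QS})
    scenarios = sorted({h for _, h in solution.upper.QS})
    if level == "lake":
        return {
            (i, h): paired_interval(
                _run_actual(solution.lower, i, h), _run_actual(solution.upper, i, h)
            )
            for i in lakes
            for h in scenarios
        }
    if level == "total":
        return {
            h: paired_interval(
                sum(_run_actual(solution.lower, i, h) for i in lakes),
                sum(_run_actual(solution.upper, i, h) for i in lakes),
            )
            for h in scenarios
        }
    raise ValueError(f"unsupported level {level!r}")


def water_shortage(
    solution: IpftspSolution, level: str = "total"
) -> Dict[object, IntervalValue]:
    """Second-stage shortages QS, paired across runs.

    Per lake and scenario the identity ``target = shortage + (actual
    supply - conveyance loss)`` holds exactly whenever delivered water is
    fully converted to area (the pond-priority branch), which the
    lexicographic solve enforces.
    """
    lakes = sorted({i for i, _ in solution.upper.QS})
    scenarios = sorted({h for _, h in solution.upper.QS})
    if level == "lake":
        return {
            (i, h): paired_interval(solution.lower.QS[i, h], solution.upper.QS[i, h])
            for i in lakes
            for h in scenarios
        }
    if level == "total":
        return {
            h: paired_interval(
                sum(solution.lower.QS[i, h] for i in lakes),
                sum(solution.upper.QS[i, h] for i in lakes),
            )
            for h in scenarios
        }
    raise ValueError(f"unsupported level {level!r}")


def habitat_area(
    solution: IpftspSolution,
    instance: ProblemInstance,
    level: str = "total",
    overrides: Optional[Dict[str, str]] = None,
) -> Dict[object, IntervalValue]:
    """Recovered suitable habitat area from the run-specific coefficients.

    Per scenario: ``sum_i C_i (QT_i - QS_ih)``; the ``"expected_target"``
    level returns the probability mixture over scenarios (the model's
    target value).  ``"region"`` groups lakes by intake (region group
    r = intake n).
    """
    realizations = {
        w: realize_parameters(instance, w, overrides) for w in _RUNS
    }
    probs = {s.scenario_id: s.probability for s in instance.scenarios}
    scenarios = sorted(probs)

    def run_area(which: str, lakes: Iterable[int], h: int) -> float:
        sol = solution.run(which)
        C = realizations[which].C
        return sum(C[i] * sol.net_supplement(i, h) for i in lakes)

    all_lakes = instance.lake_ids
    if level == "total":
        return {
            h: paired_interval(
                run_area("lower_run", all_lakes, h), run_area("upper_run", all_lakes, h)
            )
            for h in scenarios
        }
    if level == "region":
        out = {}
        for n in sorted(instance.intakes):
            group = intake_group(instance, n)
            for h in scenarios:
                out[n, h] = paired_interval(
                    run_area("lower_run", group, h), run_area("upper_run", group, h)
                )
        return out
    if level == "lake":
        return {
            (i, h): paired_interval(
                run_area("lower_run", [i], h), run_area("upper_run", [i], h)
            )
            for i in all_lakes
            for h in scenarios
        }
    if level == "expected_target":
        vals = {
            w: sum(
                probs[h] * run_area(w, all_lakes, h) for h in scenarios
            )
            for w in _RUNS
        }
        return {"target": paired_interval(vals["lower_run"], vals["upper_run"])}
    raise ValueError(f"unsupported level {level!r}")


def carrying_capacity(area: float, density: float) -> float:
    """Birds supported by ``area``: area / density, same scale prefix.

    With area in 10^3 ha and density in ha/bird the result is 10^3 birds.
    """
    if density <= 0:
        raise ValueError("bird density must be positive")
    return area / density


def flood_share(solution: IpftspSolution) -> Dict[int, IntervalValue]:
    """Flood fraction of the actual supply per scenario, paired across runs."""
    lakes = sorted({i for i, _ in solution.upper.QS})
    scenarios = sorted({h for _, h in solution.upper.QS})
    out = {}
    for h in scenarios:
        shares = []
        for which in _RUNS:
            sol = solution.run(which)
            total = sum(_run_actual(sol, i, h) for i in lakes)
            if total <= 0:
                raise ValueError(f"zero actual supply in scenario {h} ({which})")
            shares.append(sum(sol.QFD[i, h] for i in lakes) / total)
        out[h] = paired_interval(*shares)
    return out


@dataclass
class BenefitAccounting:
    esv_per_service: Dict[Tuple[int, int], IntervalValue]  # (service k, scenario h)
    esv_total: Dict[int, IntervalValue]  # per scenario
    esv_expected: IntervalValue
    carbon_per_lake: Dict[Tuple[int, int], IntervalValue]  # (lake, scenario)
    carbon_total: Dict[int, IntervalValue]
    carbon_expected: IntervalValue
    floor_violations: List[str] = field(default_factory=list)


def benefit_accounting(
    solution: IpftspSolution,
    instance: ProblemInstance,
    tol: float = 1e-6,
    overrides: Optional[Dict[str, str]] = None,
) -> BenefitAccounting:
    """Ecosystem-service value and net carbon sink achieved by the areas.

    Evaluates the benefit sums per scenario and run against the floors of
    the matching realization; a floor violated beyond ``tol`` indicates a
    solver/report mismatch and is flagged, not raised.
    """
    realizations = {w: realize_parameters(instance, w, overrides) for w in _RUNS}
    probs = {s.scenario_id: s.probability for s in instance.scenarios}
    scenarios = sorted(probs)
    services = instance.system.service_functions
    violations: List[str] = []

    def esv_lhs(which: str, k: int, h: int) -> float:
        sol, real = solution.run(which), realizations[which]
        return sum(
            sol.FA[l.lake_id, r.region_id, h]
            * r.exists
            * real.ESV.get((r.region_id, k), 0.0)
            for l in instance.lakes
            for r in l.regions
        )

    def carbon_lhs(which: str, i: int, h: int) -> float:
        sol, real = solution.run(which), realizations[which]
        lake = instance.lake(i)
        return sum(
            sol.FA[i, r.region_id, h] * r.exists * real.NCSA[i, r.region_id]
            for r in lake.regions
        )

    esv_ks: Dict[Tuple[int, int], IntervalValue] = {}
    for k in services:
        for h in scenarios:
            vals = {}
            for w in _RUNS:
                v = esv_lhs(w, k, h)
                floor = realizations[w].TEB[k]
                if v < floor - tol:
                    violations.append(
                        f"esv floor k={k} h={h} {w}: {v:.6f} < {floor:.6f}"
                    )
                vals[w] = v
            esv_ks[k, h] = paired_interval(vals["lower_run"], vals["upper_run"])
    esv_total = {
        h: paired_interval(
            sum(esv_lhs("lower_run", k, h) for k in services),
            sum(esv_lhs("upper_run", k, h) for k in services),
        )
        for h in scenarios
    }
    carbon_il: Dict[Tuple[int, int], IntervalValue] = {}
    for lake in instance.lakes:
        i = lake.lake_id
        for h in scenarios:
            vals = {}
            for w in _RUNS:
                v = carbon_lhs(w, i, h)
                floor = realizations[w].TCS[i]
                if v < floor - tol:
                    violations.append(
                        f"carbon floor lake={i} h={h} {w}: {v:.6f} < {floor:.6f}"
                    )
                vals[w] = v
            carbon_il[i, h] = paired_interval(vals["lower_run"], vals["upper_run"])
    carbon_total = {
        h: paired_interval(
            sum(carbon_lhs("lower_run", l.lake_id, h) for l in instance.lakes),
            sum(carbon_lhs("upper_run", l.lake_id, h) for l in instance.lakes),
        )
        for h in scenarios
    }

    def expected(totals: Dict[int, IntervalValue]) -> IntervalValue:
        # probability-weighted mixture per run is not available from the
        # paired totals; recompute per run to keep run alignment
        return paired_interval(
            sum(probs[h] * totals[h].lower for h in scenarios),
            sum(probs[h] * totals[h].upper for h in scenarios),
        )

    return BenefitAccounting(
        esv_per_service=esv_ks,
        esv_total=esv_total,
        esv_expected=expected(esv_total),
        carbon_per_lake=carbon_il,
        carbon_total=carbon_total,
        carbon_expected=expected(carbon_total),
        floor_violations=violations,
    )


def compare_schemes(
    values: Dict[int, RunPair],
    reference: Dict[int, float] | float,
    iptsp_reference: Optional[Dict[int, IntervalValue]] = None,
) -> Dict[str, Dict[int, object]]:
    """Percent change vs a crisp reference and width reduction vs interval
    reference, per key (typically scenario id)."""
    out: Dict[str, Dict[int, object]] = {"percent_change": {}}
    for key, pair in values.items():
        ref = reference[key] if isinstance(reference, dict) else reference
        out["percent_change"][key] = paired_interval(
            pair.lower_run / ref - 1.0, pair.upper_run / ref - 1.0
        )
    if iptsp_reference is not None:
        out["width_reduction"] = {
            key: width_reduction_ratio(_pair(pair), iptsp_reference[key])
            for key, pair in values.items()
            if key in iptsp_reference
        }
    return out


# ---------------------------------------------------------------------------
# table-level accounting (works on printed fixture tables too)
# ---------------------------------------------------------------------------


@dataclass
class SupplyAccounting:
    """Supply accounting derived from per-intake targets and supply tables."""

    total_target: float
    actual_total: Dict[int, IntervalValue]  # per scenario
    shortage_total: Dict[int, IntervalValue]
    flood_share: Dict[int, IntervalValue]  # fractions
    relative_range: Dict[int, float]  # fractions
    width_reduction: Dict[int, float] = field(default_factory=dict)


def supply_accounting(
    targets: Dict[int, float],
    local_normal: Dict[Tuple[int, int], RunPair],
    flood: Dict[Tuple[int, int], RunPair],
    iptsp_supply: Optional[Dict[int, RunPair]] = None,
) -> SupplyAccounting:
    """Aggregate per-intake supply tables into the headline accounting.

    Inputs are run-aligned pairs per (intake, scenario); every output
    interval is computed within a run first and paired afterwards.
    """
    intakes = sorted(targets)
    scenarios = sorted({h for _, h in local_normal})
    total_target = sum(targets.values())

    def run_total(table, h, run_attr):
        return sum(getattr(table[n, h], run_attr) for n in intakes)

    actual, shortage, share, rel = {}, {}, {}, {}
    reduction = {}
    for h in scenarios:
        per_run_actual = {}
        per_run_flood = {}
        for attr in ("lower_run", "upper_run"):
            ln = run_total(local_normal, h, attr)
            fl = run_total(flood, h, attr)
            per_run_actual[attr] = ln + fl
            per_run_flood[attr] = fl
        actual[h] = paired_interval(
            per_run_actual["lower_run"], per_run_actual["upper_run"]
        )
        shortage[h] = paired_interval(
            total_target - per_run_actual["lower_run"],
            total_target - per_run_actual["upper_run"],
        )
        share[h] = paired_interval(
            per_run_flood["lower_run"] / per_run_actual["lower_run"],
            per_run_flood["upper_run"] / per_run_actual["upper_run"],
        )
        rel[h] = interval_relative_range(actual[h])
        if iptsp_supply is not None and h in iptsp_supply:
            reduction[h] = width_reduction_ratio(actual[h], _pair(iptsp_supply[h]))

    return SupplyAccounting(
        total_target=total_target,
        actual_total=actual,
        shortage_total=shortage,
        flood_share=share,
        relative_range=rel,
        width_reduction=reduction,
    )


def fixture_supply_accounting(fixtures) -> SupplyAccounting:
    """Supply accounting from printed fixture tables (run-aligned totals)."""
    scenarios = sorted(fixtures.total_local_normal)
    return supply_accounting(
        {0: fixtures.total_target},
        {(0, h): fixtures.total_local_normal[h] for h in scenarios},
        {(0, h): fixtures.total_flood[h] for h in scenarios},
        fixtures.iptsp_supply,
    )


# ---------------------------------------------------------------------------
# consolidated report
# ---------------------------------------------------------------------------


@dataclass
class ReportBundle:
    """All derived tables of one solved plan."""

    lam: IntervalValue
    total_target: float
    intake_targets: Dict[int, float]
    supply: SupplyAccounting
    habitat_region: Dict[Tuple[int, int], IntervalValue]
    habitat_total: Dict[int, IntervalValue]
    habitat_target_value: IntervalValue
    capacity_total: Dict[int, IntervalValue]  # 10^3 birds
    capacity_region: Dict[Tuple[int, int], IntervalValue]
    function_region_area: Dict[Tuple[int, int], IntervalValue]  # (j, h)
    total_area: Dict[int, IntervalValue]
    benefits: BenefitAccounting
    comparisons: Dict[str, object] = field(default_factory=dict)
    notices: List[str] = field(default_factory=list)


def build_report(
    instance: ProblemInstance,
    solution: IpftspSolution,
    overrides: Optional[Dict[str, str]] = None,
) -> ReportBundle:
    """Compute every derived table from a solved plan."""
    scenarios = sorted(s.scenario_id for s in instance.scenarios)
    intakes = sorted(instance.intakes)
    region_ids = instance.region_ids
    density = instance.system.bird_density

    intake_targets = {
        n: sum(solution.upper.QT[i] for i in intake_group(instance, n))
        for n in intakes
    }

    def run_table(fn) -> Dict[Tuple[int, int], RunPair]:
        return {
            (n, h): RunPair(fn(solution.lower, n, h), fn(solution.upper, n, h))
            for n in intakes
            for h in scenarios
        }

    local_normal = run_table(
        lambda sol, n, h: sum(
            sol.QID[i, h] + sol.QND[i, h] for i in intake_group(instance, n)
        )
    )
    flood = run_table(
        lambda sol, n, h: sum(sol.QFD[i, h] for i in intake_group(instance, n))
    )
    iptsp = instance.system.reference_iptsp
    iptsp_supply = None
    if iptsp is not None and iptsp.actual_supply:
        iptsp_supply = {
            h: RunPair(v.lower, v.upper) for h, v in iptsp.actual_supply.items()
        }
    supply = supply_accounting(intake_targets, local_normal, flood, iptsp_supply)
    # table-level accounting equates shortage with target minus actual
    # supply, which is loss-free; from a solved plan the shortage is the
    # recourse variable itself (target = shortage + actual - conveyance loss)
    supply.shortage_total = water_shortage(solution, "total")

    habitat_region = habitat_area(solution, instance, "region", overrides)
    habitat_total = habitat_area(solution, instance, "total", overrides)
    habitat_target_value = habitat_area(
        solution, instance, "expected_target", overrides
    )["target"]
    capacity_total = {
        h: IntervalValue(
            carrying_capacity(v.lower, density), carrying_capacity(v.upper, density)
        )
        for h, v in habitat_total.items()
    }
    capacity_region = {
        key: IntervalValue(
            carrying_capacity(v.lower, density), carrying_capacity(v.upper, density)
        )
        for key, v in habitat_region.items()
    }

    def area_sum(sol: SubmodelSolution, j: int, h: int) -> float:
        return sum(
            sol.FA[l.lake_id, j, h]
            for l in instance.lakes
            if any(r.region_id == j for r in l.regions)
        )

    function_region_area = {
        (j, h): paired_interval(
            area_sum(solution.lower, j, h), area_sum(solution.upper, j, h)
        )
        for j in region_ids
        for h in scenarios
    }
    total_area = {
        h: paired_interval(
            sum(area_sum(solution.lower, j, h) for j in region_ids),
            sum(area_sum(solution.upper, j, h) for j in region_ids),
        )
        for h in scenarios
    }

    benefits = benefit_accounting(solution, instance, overrides=overrides)

    comparisons: Dict[str, object] = {}
    notices: List[str] = []
    ref = instance.system.reference_scheme
    if ref is not None and ref.habitat_area:
        hab_pairs = {
            h: RunPair(
                sum(
                    realize_parameters(instance, "lower_run", overrides).C[i]
                    * solution.lower.net_supplement(i, h)
                    for i in instance.lake_ids
                ),
                sum(
                    realize_parameters(instance, "upper_run", overrides).C[i]
                    * solution.upper.net_supplement(i, h)
                    for i in instance.lake_ids
                ),
            )
            for h in scenarios
        }
        comparisons["habitat_vs_recommended"] = compare_schemes(
            hab_pairs,
            ref.habitat_area,
            iptsp.habitat_area if iptsp is not None else None,
        )
    else:
        notices.append("no recommended-scheme reference; comparison block omitted")
    if iptsp is None:
        notices.append("no antecedent-model reference; width reductions omitted")

    return ReportBundle(
        lam=solution.lam,
        total_target=sum(intake_targets.values()),
        intake_targets=intake_targets,
        supply=supply,
        habitat_region=habitat_region,
        habitat_total=habitat_total,
        habitat_target_value=habitat_target_value,
        capacity_total=capacity_total,
        capacity_region=capacity_region,
        function_region_area=function_region_area,
        total_area=total_area,
        benefits=benefits,
        comparisons=comparisons,
        notices=notices,
    )


def _iv(v: IntervalValue, digits: int = 2) -> str:
    return f"({round_half_up(v.lower, digits):.{digits}f}, {round_half_up(v.upper, digits):.{digits}f})"


def write_report(bundle: ReportBundle, directory: str | Path) -> None:
    """One CSV per derived table plus a consolidated markdown summary."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    scen = sorted(bundle.habitat_total)

    pd.DataFrame(
        [
            {
                "scenario": h,
                "actual_lower": bundle.supply.actual_total[h].lower,
                "actual_upper": bundle.supply.actual_total[h].upper,
                "shortage_lower": bundle.supply.shortage_total[h].lower,
                "shortage_upper": bundle.supply.shortage_total[h].upper,
                "flood_share_pct_lower": as_percent(bundle.supply.flood_share[h].lower),
                "flood_share_pct_upper": as_percent(bundle.supply.flood_share[h].upper),
                "relative_range_pct": as_percent(bundle.supply.relative_range[h]),
                "width_reduction_pct": as_percent(bundle.supply.width_reduction[h])
                if h in bundle.supply.width_reduction
                else None,
            }
            for h in scen
        ]
    ).to_csv(d / "supply_accounting.csv", index=False)

    pd.DataFrame(
        [
            {
                "region_group": r,
                "scenario": h,
                "habitat_lower": v.lower,
                "habitat_upper": v.upper,
                "capacity_lower": bundle.capacity_region[r, h].lower,
                "capacity_upper": bundle.capacity_region[r, h].upper,
            }
            for (r, h), v in sorted(bundle.habitat_region.items())
        ]
    ).to_csv(d / "habitat_capacity.csv", index=False)

    pd.DataFrame(
        [
            {
                "region": j,
                "scenario": h,
                "area_lower": v.lower,
                "area_upper": v.upper,
            }
            for (j, h), v in sorted(bundle.function_region_area.items())
        ]
    ).to_csv(d / "function_region_areas.csv", index=False)

    pd.DataFrame(
        [
            {
                "scenario": h,
                "esv_lower": bundle.benefits.esv_total[h].lower,
                "esv_upper": bundle.benefits.esv_total[h].upper,
                "carbon_lower": bundle.benefits.carbon_total[h].lower,
                "carbon_upper": bundle.benefits.carbon_total[h].upper,
            }
            for h in scen
        ]
    ).to_csv(d / "benefits.csv", index=False)

    (d / "summary.md").write_text(report_markdown(bundle))


def report_markdown(bundle: ReportBundle) -> str:
    """Human-readable summary mirroring the layout of the printed tables."""
    scen = sorted(bundle.habitat_total)
    lines = [
        "# Plan summary",
        "",
        f"- fuzzy membership lambda: {_iv(bundle.lam)}",
        f"- total first-stage target: {round_half_up(bundle.total_target):.2f} x10^4 m^3",
        f"- habitat target value: {_iv(bundle.habitat_target_value)} x10^3 ha",
        "",
        "| scenario | actual supply (10^4 m^3) | shortage | flood share | habitat (10^3 ha) | capacity (10^3 birds) |",
        "|---|---|---|---|---|---|",
    ]
    for h in scen:
        fs = bundle.supply.flood_share[h]
        lines.append(
            f"| {h} | {_iv(bundle.supply.actual_total[h])} "
            f"| {_iv(bundle.supply.shortage_total[h])} "
            f"| ({as_percent(fs.lower):.2f}%, {as_percent(fs.upper):.2f}%) "
            f"| {_iv(bundle.habitat_total[h])} "
            f"| {_iv(bundle.capacity_total[h])} |"
        )
    if bundle.supply.width_reduction:
        lines += ["", "Decision-space reduction vs the antecedent interval model:"]
        for h in scen:
            if h in bundle.supply.width_reduction:
                lines.append(
                    f"- scenario {h}: {as_percent(bundle.supply.width_reduction[h]):.2f}%"
                )
    for notice in bundle.notices:
        lines.append(f"\n> {notice}")
    return "\n".join(lines) + "\n"
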