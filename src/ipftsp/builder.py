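"""Transformation of a problem instance into deterministic sub-models.

The interactive two-step algorithm replaces every interval coefficient by
one of its endpoints, producing two deterministic mixed-integer programs:
the *upper run* takes the favorable endpoint of each parameter and yields
the optimistic bound of every result, the *lower run* takes the adverse
endpoints and yields the conservative bound.  Fuzzy (flexible) bounds are
not collapsed: they enter every fuzzified right-hand side linearly through
the scalar membership variable lambda, which both sub-models maximize.

Endpoint conventions (upper run; the lower run mirrors them):

====================  =========  =============================================
parameter             endpoint   why it is favorable
====================  =========  =============================================
habitat coefficient   upper      more habitat per unit of delivered water
per-area demand QR    lower      each hectare needs less water
caps QI, QN, QTF      upper      more water available
supply loss QL        lower      less water lost in conveyance
benefit rates ESV,    upper      floors easier to satisfy
NCSA
floors TEB, TCS       lower      weaker benefit requirements
====================  =========  =============================================

The water-supplement priority rules (ponds before reed/marsh, reed before
marsh) are conditional constraints; they are linearized with big-M
indicator pairs using a per-lake certified bound on every expression
involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

from ._linmodel import LinearModel
from .instance import ProblemInstance, intake_group

__all__ = [
    "ParameterRealization",
    "DeterministicSubmodel",
    "realize_parameters",
    "build_submodel",
    "big_m_value",
]

#: per parameter family, the endpoint the *upper* (favorable) run takes
FAVORABLE_ENDPOINTS: Dict[str, str] = {
    "C": "upper",
    "QR": "lower",
    "QL": "lower",
    "QI": "upper",
    "QN": "upper",
    "QTF": "upper",
    "ESV": "upper",
    "NCSA": "upper",
    "TEB": "lower",
    "TCS": "lower",
}

_OPPOSITE = {"lower": "upper", "upper": "lower"}


@dataclass
class ParameterRealization:
    """Crisp endpoint choices for every interval parameter of one run."""

    which: str  # "upper_run" or "lower_run"
    C: Dict[int, float]
    QR: Dict[Tuple[int, int], float]
    QL: Dict[int, float]
    QI: Dict[int, float]
    QN: Dict[int, float]
    QTF: Dict[Tuple[int, int], float]  # (intake, scenario)
    ESV: Dict[Tuple[int, int], float]  # (region j, service k)
    TEB: Dict[int, float]
    NCSA: Dict[Tuple[int, int], float]  # (lake, region)
    TCS: Dict[int, float]
    endpoints: Dict[str, str] = field(default_factory=dict)


def realize_parameters(
    instance: ProblemInstance,
    which: str,
    overrides: Optional[Dict[str, str]] = None,
) -> ParameterRealization:
    """Choose interval endpoints for one deterministic run.

    ``overrides`` maps a parameter family (e.g. ``"C"``) to the endpoint
    the *upper* run should take; the lower run always takes the opposite
    endpoint of whatever the upper run takes.
    """
    if which not in ("upper_run", "lower_run"):
        raise ValueError(f"run must be 'upper_run' or 'lower_run', got {which!r}")
    fav = dict(FAVORABLE_ENDPOINTS)
    if overrides:
        unknown = set(overrides) - set(fav)
        if unknown:
            raise KeyError(f"unknown parameter families in overrides: {sorted(unknown)}")
        fav.update(overrides)
    pick = fav if which == "upper_run" else {k: _OPPOSITE[v] for k, v in fav.items()}

    C = {l.lake_id: l.habitat_coefficient.endpoint(pick["C"]) for l in instance.lakes}
    QL = {l.lake_id: l.supply_loss.endpoint(pick["QL"]) for l in instance.lakes}
    QI = {l.lake_id: l.local_supply_cap.endpoint(pick["QI"]) for l in instance.lakes}
    QN = {l.lake_id: l.normal_supply_cap.endpoint(pick["QN"]) for l in instance.lakes}
    QR = {
        (l.lake_id, r.region_id): r.water_demand_per_area.endpoint(pick["QR"])
        for l in instance.lakes
        for r in l.regions
    }
    NCSA = {
        (l.lake_id, r.region_id): r.carbon_sink_per_area.endpoint(pick["NCSA"])
        for l in instance.lakes
        for r in l.regions
    }
    TCS = {l.lake_id: l.carbon_sink_floor.endpoint(pick["TCS"]) for l in instance.lakes}
    QTF = {
        (n, s.scenario_id): s.flood_available[n].endpoint(pick["QTF"])
        for s in instance.scenarios
        for n in s.flood_available
    }
    ESV = {
        (j, k): v.endpoint(pick["ESV"])
        for j, per_k in instance.system.esv_per_area.items()
        for k, v in per_k.items()
    }
    TEB = {k: v.endpoint(pick["TEB"]) for k, v in instance.system.esv_floor.items()}
    return ParameterRealization(
        which=which, C=C, QR=QR, QL=QL, QI=QI, QN=QN, QTF=QTF,
        ESV=ESV, TEB=TEB, NCSA=NCSA, TCS=TCS, endpoints=pick,
    )


def big_m_value(instance: ProblemInstance, lake_id: int) -> float:
    """Certified bound on every linear expression in a lake's priority block.

    Sums the largest possible water turnover of the lake: full planning
    area at the loosest bound times the highest per-area demand, plus all
    supply capacities at their upper endpoints and the conveyance loss.
    """
    lake = instance.lake(lake_id)
    qr_up = max((r.water_demand_per_area.upper for r in lake.regions), default=0.0)
    area_term = qr_up * lake.total_planning_area.a
    flood = max(
        (s.flood_available[lake.intake_id].upper
         for s in instance.scenarios
         if lake.intake_id in s.flood_available),
        default=0.0,
    )
    m = (
        area_term
        + lake.local_supply_cap.upper
        + lake.normal_supply_cap.upper
        + lake.supply_loss.upper
        + flood
    )
    if m <= 0:
        raise ValueError(f"nonpositive big-M for lake {lake_id}; check capacities")
    return m


@dataclass
class DeterministicSubmodel:
    """One deterministic sub-model: a MILP maximizing lambda.

    Wraps the compiled linear model together with variable index maps so
    solutions can be read back by (lake, region, scenario) keys.
    """

    instance: ProblemInstance
    realization: ParameterRealization
    model: LinearModel
    lam: int
    QT: Dict[int, int]
    QS: Dict[Tuple[int, int], int]
    QID: Dict[Tuple[int, int], int]
    QND: Dict[Tuple[int, int], int]
    QFD: Dict[Tuple[int, int], int]
    FA: Dict[Tuple[int, int, int], int]
    d1: Dict[Tuple[int, int], int]
    d2: Dict[Tuple[int, int], int]
    big_M: Dict[int, float]
    fixed_QT: Optional[Dict[int, float]] = None

    def family_counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for con in self.model.constraints:
            out[con.family] = out.get(con.family, 0) + 1
        return out


#: region ids with pond priority (fish pond, crab pond) and the reed/marsh pair
POND_REGIONS = (1, 2)
REED_REGION = 3
MARSH_REGION = 4


def build_submodel(
    instance: ProblemInstance,
    realization: ParameterRealization,
    fixed_QT: Optional[Dict[int, float]] = None,
) -> DeterministicSubmodel:
    """Emit the full deterministic MILP for one run.

    ``fixed_QT`` pins the first-stage targets (used for the lower run after
    the upper run has fixed them).  All fuzzified right-hand sides are
    linear in the membership variable lambda; the priority conditionals
    become big-M indicator pairs with binaries d1 (ponds reached their
    fuzzified minimum) and d2 (reed reached its fuzzified minimum).
    """
    if fixed_QT is None:
        fixed_QT = instance.fixed_first_stage
    m = LinearModel(maximize=True)
    sys_ = instance.system
    scen = {s.scenario_id: s for s in instance.scenarios}
    H = list(scen)

    lam = m.add_var("lam", 0.0, 1.0)
    m.set_objective({lam: 1.0}, maximize=True)

    big_M = {l.lake_id: big_m_value(instance, l.lake_id) for l in instance.lakes}

    QT: Dict[int, int] = {}
    for lake in instance.lakes:
        i = lake.lake_id
        if fixed_QT is not None and i in fixed_QT:
            v = float(fixed_QT[i])
            QT[i] = m.add_var(f"QT[{i}]", v, v)
        else:
            # targets beyond the largest deliverable volume are meaningless;
            # the explicit cap keeps the lexicographic target selection bounded
            flood = max(realization.QTF.get((lake.intake_id, h), 0.0) for h in H)
            ub = realization.QI[i] + realization.QN[i] + flood
            QT[i] = m.add_var(f"QT[{i}]", 0.0, ub)

    QS, QID, QND, QFD = {}, {}, {}, {}
    FA: Dict[Tuple[int, int, int], int] = {}
    d1, d2 = {}, {}
    for lake in instance.lakes:
        i = lake.lake_id
        for h in H:
            QS[i, h] = m.add_var(f"QS[{i},{h}]")
            QID[i, h] = m.add_var(f"QID[{i},{h}]")
            QND[i, h] = m.add_var(f"QND[{i},{h}]")
            QFD[i, h] = m.add_var(f"QFD[{i},{h}]")
            d1[i, h] = m.add_var(f"d1[{i},{h}]", 0.0, 1.0, integer=True)
            d2[i, h] = m.add_var(f"d2[{i},{h}]", 0.0, 1.0, integer=True)
            for r in lake.regions:
                FA[i, r.region_id, h] = m.add_var(f"FA[{i},{r.region_id},{h}]")

    f = sys_.habitat_target  # (f-, f+) from the antecedent interval model

    # habitat-area target: sum_i C*QT - sum_ih P*C*QS >= f- + lam*(f+ - f-)
    coeffs: Dict[int, float] = {lam: -f.width}
    for lake in instance.lakes:
        i = lake.lake_id
        coeffs[QT[i]] = realization.C[i]
        for h in H:
            coeffs[QS[i, h]] = -scen[h].probability * realization.C[i]
    m.add_constraint("habitat_target", coeffs, ">=", f.lower, family="habitat_target")

    for lake in instance.lakes:
        i = lake.lake_id
        M = big_M[i]
        regions = sorted(lake.regions, key=lambda r: r.region_id)
        for h in H:
            # minimum water demand at the fuzzified minimum areas
            base = sum(
                realization.QR[i, r.region_id] * r.area_min.b for r in regions
            )
            slope = sum(
                realization.QR[i, r.region_id] * r.area_min.spread for r in regions
            )
            m.add_constraint(
                f"min_demand[{i},{h}]",
                {QT[i]: 1.0, QS[i, h]: -1.0, lam: -slope},
                ">=",
                base,
                family="min_demand",
            )
            # net supplement cannot exceed delivered water less losses
            m.add_constraint(
                f"supply_balance[{i},{h}]",
                {QT[i]: 1.0, QS[i, h]: -1.0, QID[i, h]: -1.0,
                 QND[i, h]: -1.0, QFD[i, h]: -1.0},
                "<=",
                -realization.QL[i],
                family="supply_balance",
            )
            m.add_constraint(
                f"local_cap[{i},{h}]", {QID[i, h]: 1.0}, "<=",
                realization.QI[i], family="local_cap",
            )
            m.add_constraint(
                f"normal_cap[{i},{h}]", {QND[i, h]: 1.0}, "<=",
                realization.QN[i], family="normal_cap",
            )
            m.add_constraint(
                f"shortage_le_target[{i},{h}]",
                {QS[i, h]: 1.0, QT[i]: -1.0}, "<=", 0.0,
                family="shortage_le_target",
            )

            # ---- priority block: ponds before reed/marsh (indicator d1) ----
            ponds = [r for r in regions if r.region_id in POND_REGIONS]
            others = [r for r in regions if r.region_id not in POND_REGIONS]
            if ponds and others:
                pb = sum(r.area_min.b for r in ponds)
                pw = sum(r.area_min.spread for r in ponds)
                lo = {FA[i, r.region_id, h]: 1.0 for r in ponds}
                lo[lam] = -pw
                lo[d1[i, h]] = -M
                m.add_constraint(
                    f"pond_reach_lo[{i},{h}]", lo, ">=", pb - M,
                    family="priority_ponds",
                )
                hi = {FA[i, r.region_id, h]: 1.0 for r in ponds}
                hi[lam] = -pw
                hi[d1[i, h]] = -M
                m.add_constraint(
                    f"pond_reach_hi[{i},{h}]", hi, "<=", pb,
                    family="priority_ponds",
                )
                # d1 = 1: delivered water is fully converted to area
                eq = {FA[i, r.region_id, h]: realization.QR[i, r.region_id]
                      for r in regions}
                eq.update({QID[i, h]: -1.0, QND[i, h]: -1.0, QFD[i, h]: -1.0})
                eq_hi = dict(eq)
                eq_hi[d1[i, h]] = M
                m.add_constraint(
                    f"pond_full_use_hi[{i},{h}]", eq_hi, "<=",
                    -realization.QL[i] + M, family="priority_ponds",
                )
                eq_lo = dict(eq)
                eq_lo[d1[i, h]] = -M
                m.add_constraint(
                    f"pond_full_use_lo[{i},{h}]", eq_lo, ">=",
                    -realization.QL[i] - M, family="priority_ponds",
                )
                # d1 = 0: no water reaches reed/marsh
                m.add_constraint(
                    f"pond_else[{i},{h}]",
                    {**{FA[i, r.region_id, h]: realization.QR[i, r.region_id]
                        for r in others},
                     d1[i, h]: -M},
                    "<=",
                    0.0,
                    family="priority_ponds",
                )

            # ---- priority block: reed before marsh (indicator d2) ----
            reed = next((r for r in regions if r.region_id == REED_REGION), None)
            marsh = next((r for r in regions if r.region_id == MARSH_REGION), None)
            if reed is not None and marsh is not None:
                m.add_constraint(
                    f"reed_reach_lo[{i},{h}]",
                    {FA[i, REED_REGION, h]: 1.0, lam: -reed.area_min.spread,
                     d2[i, h]: -M},
                    ">=",
                    reed.area_min.b - M,
                    family="priority_reed",
                )
                m.add_constraint(
                    f"reed_reach_hi[{i},{h}]",
                    {FA[i, REED_REGION, h]: 1.0, lam: -reed.area_min.spread,
                     d2[i, h]: -M},
                    "<=",
                    reed.area_min.b,
                    family="priority_reed",
                )
                m.add_constraint(
                    f"marsh_else[{i},{h}]",
                    {FA[i, MARSH_REGION, h]: realization.QR[i, MARSH_REGION],
                     d2[i, h]: -M},
                    "<=",
                    0.0,
                    family="priority_reed",
                )

            # ---- function-region areas ----
            tfa = lake.total_planning_area
            m.add_constraint(
                f"area_total[{i},{h}]",
                {**{FA[i, r.region_id, h]: 1.0 for r in regions},
                 lam: tfa.spread},
                "<=",
                tfa.a,
                family="area_total",
            )
            for r in regions:
                m.add_constraint(
                    f"area_max[{i},{r.region_id},{h}]",
                    {FA[i, r.region_id, h]: 1.0, lam: r.area_max.spread},
                    "<=",
                    r.area_max.a,
                    family="area_max",
                )
            m.add_constraint(
                f"area_vs_habitat[{i},{h}]",
                {**{FA[i, r.region_id, h]: 1.0 for r in regions},
                 QT[i]: -realization.C[i], QS[i, h]: realization.C[i]},
                ">=",
                0.0,
                family="area_vs_habitat",
            )
            m.add_constraint(
                f"water_area_balance[{i},{h}]",
                {**{FA[i, r.region_id, h]: realization.QR[i, r.region_id]
                    for r in regions},
                 QT[i]: -1.0, QS[i, h]: 1.0},
                "==",
                0.0,
                family="water_area_balance",
            )
            # carbon-sink floor per lake
            m.add_constraint(
                f"carbon_floor[{i},{h}]",
                {FA[i, r.region_id, h]: r.exists * realization.NCSA[i, r.region_id]
                 for r in regions},
                ">=",
                realization.TCS[i],
                family="carbon_floor",
            )

    # flood availability per intake group
    for n in instance.intakes:
        group = intake_group(instance, n)
        for h in H:
            m.add_constraint(
                f"flood_cap[{n},{h}]",
                {QFD[i, h]: 1.0 for i in group},
                "<=",
                realization.QTF[n, h],
                family="flood_cap",
            )

    # ecosystem-service benefit floors per service function
    for k in sys_.service_functions:
        for h in H:
            coeffs = {}
            for lake in instance.lakes:
                for r in lake.regions:
                    esv = realization.ESV.get((r.region_id, k), 0.0)
                    coeffs[FA[lake.lake_id, r.region_id, h]] = r.exists * esv
            m.add_constraint(
                f"esv_floor[{k},{h}]", coeffs, ">=",
                realization.TEB[k], family="esv_floor",
            )

    return DeterministicSubmodel(
        instance=instance, realization=realization, model=m,
        lam=lam, QT=QT, QS=QS, QID=QID, QND=QND, QFD=QFD, FA=FA,
        d1=d1, d2=d2, big_M=big_M, fixed_QT=fixed_QT,
    )
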