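"""Interactive two-step solution of the interval-fuzzy planning model.

Step 1 solves the favorable (upper) sub-model with the first-stage water
targets free, which fixes the crisp targets QT and the optimistic
membership lambda+.  Step 2 re-solves the adverse (lower) sub-model with
QT pinned to the step-1 values, yielding the conservative membership
lambda- and the lower-bound recourse.  Paired results form the reported
intervals.

Because "maximize lambda" leaves the continuous variables massively
degenerate, each sub-model is solved lexicographically: after the optimal
membership is found, lambda and the priority indicators are fixed and a
secondary LP picks, among the lambda-optimal points, the one with the
largest expected net water supplement, the smallest targets achieving it,
minimal deliveries, and flood water preferred over local over normal
supply (mirroring the flood-first priority of the underlying scheme).
Repeated runs are therefore bit-identical per backend.

An independent brute-force oracle (:func:`bisection_oracle`) verifies the
max-lambda optimum on small instances by bisecting lambda and testing
feasibility through explicit enumeration of all indicator patterns, each
reduced to a plain LP; it never touches the MILP path.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import linprog

from .builder import (
    DeterministicSubmodel,
    MARSH_REGION,
    POND_REGIONS,
    REED_REGION,
    ParameterRealization,
    build_submodel,
    realize_parameters,
)
from .fuzzy import (
    FuzzyBound,
    IntervalValue,
    paired_interval,
    relaxed_capacity,
    relaxed_requirement,
)
from .instance import ProblemInstance, instance_hash, intake_group

__all__ = [
    "SolveOptions",
    "SubmodelSolution",
    "IpftspSolution",
    "InfeasibleSubmodelError",
    "solve_submodel",
    "solve_ipftsp",
    "bisection_oracle",
    "verify_solution",
    "VerificationReport",
    "solution_to_json",
    "solution_from_json",
]

#: secondary-objective weights: tiny source costs enforce flood-first supply
_EPS_SRC = 1e-4
_SRC_COST = {"QFD": 1.0, "QID": 2.0, "QND": 3.0}
_EPS_QS = 1e-4


class InfeasibleSubmodelError(RuntimeError):
    """A deterministic sub-model has no feasible point even at lambda = 0."""

    def __init__(self, which: str, diagnosis: List[str]):
        self.which = which
        self.diagnosis = diagnosis
        msg = f"{which} sub-model infeasible"
        if diagnosis:
            msg += "; binding constraint families: " + ", ".join(diagnosis)
        super().__init__(msg)


@dataclass
class SolveOptions:
    fix_first_stage: bool = True  # pin QT in the lower run to the upper-run optimum
    overrides: Optional[Dict[str, str]] = None  # endpoint overrides per family
    feasibility_tol: float = 1e-7
    residual_tol: float = 1e-6


@dataclass
class SubmodelSolution:
    which: str
    lam_opt: float
    QT: Dict[int, float]
    QS: Dict[Tuple[int, int], float]
    QID: Dict[Tuple[int, int], float]
    QND: Dict[Tuple[int, int], float]
    QFD: Dict[Tuple[int, int], float]
    FA: Dict[Tuple[int, int, int], float]
    d1: Dict[Tuple[int, int], int]
    d2: Dict[Tuple[int, int], int]
    status: str = "optimal"
    residuals: Dict[str, float] = field(default_factory=dict)

    @property
    def max_residual(self) -> float:
        return max(self.residuals.values(), default=0.0)

    def net_supplement(self, i: int, h: int) -> float:
        """Optimal water supplement QT_i - QS_ih of one lake and scenario."""
        return self.QT[i] - self.QS[i, h]


@dataclass
class IpftspSolution:
    lower: SubmodelSolution
    upper: SubmodelSolution
    lam: IntervalValue
    Q: Dict[Tuple[int, int], IntervalValue]  # net supplement intervals
    provenance: Dict[str, object] = field(default_factory=dict)

    def run(self, which: str) -> SubmodelSolution:
        if which == "lower_run":
            return self.lower
        if which == "upper_run":
            return self.upper
        raise ValueError(f"unknown run {which!r}")


def _extract(sub: DeterministicSubmodel, x: np.ndarray) -> SubmodelSolution:
    g = lambda idx: float(x[idx])
    return SubmodelSolution(
        which=sub.realization.which,
        lam_opt=g(sub.lam),
        QT={i: g(v) for i, v in sub.QT.items()},
        QS={k: g(v) for k, v in sub.QS.items()},
        QID={k: g(v) for k, v in sub.QID.items()},
        QND={k: g(v) for k, v in sub.QND.items()},
        QFD={k: g(v) for k, v in sub.QFD.items()},
        FA={k: g(v) for k, v in sub.FA.items()},
        d1={k: int(round(g(v))) for k, v in sub.d1.items()},
        d2={k: int(round(g(v))) for k, v in sub.d2.items()},
    )


def _diagnose(sub: DeterministicSubmodel) -> List[str]:
    """Localize infeasibility by dropping constraint families softest-first."""
    order = ["esv_floor", "carbon_floor", "min_demand", "habitat_target"]
    dropped: List[str] = []
    model = sub.model
    for family in order:
        model = model.drop_family(family)
        dropped.append(family)
        if model.solve().feasible:
            return dropped
    return dropped + ["physical_balance"]


def solve_submodel(
    instance: ProblemInstance,
    which: str,
    fixed_QT: Optional[Dict[int, float]] = None,
    overrides: Optional[Dict[str, str]] = None,
) -> SubmodelSolution:
    """Solve one deterministic sub-model lexicographically.

    Phase 1 maximizes lambda (MILP).  Phase 2 fixes lambda and the
    indicator pattern and re-optimizes the continuous variables with the
    secondary objective described in the module docstring, so that the
    reported targets, deliveries and shortages are unique and the supply
    accounting is tight.
    """
    realization = realize_parameters(instance, which, overrides)
    sub = build_submodel(instance, realization, fixed_QT=fixed_QT)
    model = sub.model
    first = model.solve()
    if not first.feasible:
        raise InfeasibleSubmodelError(which, _diagnose(sub))
    lam_opt = float(first.x[sub.lam])

    # phase 2: pin lambda and the indicator pattern, re-optimize continuously
    saved_bounds = (list(model.lb), list(model.ub))
    saved_obj = dict(model.objective)
    model.set_var_bounds(sub.lam, lam_opt, lam_opt)
    for dmap in (sub.d1, sub.d2):
        for idx in dmap.values():
            val = float(round(first.x[idx]))
            model.set_var_bounds(idx, val, val)
    probs = {s.scenario_id: s.probability for s in instance.scenarios}
    obj2: Dict[int, float] = {}
    for i, idx in sub.QT.items():
        obj2[idx] = 1.0
    for (i, h), idx in sub.QS.items():
        obj2[idx] = -probs[h] - _EPS_QS
    for name, vmap in (("QID", sub.QID), ("QND", sub.QND), ("QFD", sub.QFD)):
        for idx in vmap.values():
            obj2[idx] = -_EPS_SRC * _SRC_COST[name]
    # the area split between regions can stay degenerate once the net water
    # is fixed; a vanishing region-ordered cost pins a unique allocation
    for (i, j, h), idx in sub.FA.items():
        obj2[idx] = -1e-6 * j
    model.set_objective(obj2, maximize=True)
    second = model.solve()
    x = second.x if second.feasible else first.x

    model.lb, model.ub = saved_bounds
    model.objective = saved_obj
    solution = _extract(sub, x)
    solution.lam_opt = lam_opt
    solution.residuals = model.residuals(x)
    return solution


def solve_ipftsp(
    instance: ProblemInstance, options: Optional[SolveOptions] = None
) -> IpftspSolution:
    """Two-step interactive solution; returns the paired interval solution."""
    options = options or SolveOptions()
    upper = solve_submodel(
        instance, "upper_run",
        fixed_QT=instance.fixed_first_stage, overrides=options.overrides,
    )
    lower_fixed = upper.QT if options.fix_first_stage else instance.fixed_first_stage
    lower = solve_submodel(
        instance, "lower_run", fixed_QT=lower_fixed, overrides=options.overrides,
    )
    Q = {
        key: paired_interval(lower.net_supplement(*key), upper.net_supplement(*key))
        for key in upper.QS
    }
    return IpftspSolution(
        lower=lower,
        upper=upper,
        lam=paired_interval(lower.lam_opt, upper.lam_opt),
        Q=Q,
        provenance={
            "instance_hash": instance_hash(instance),
            "fix_first_stage": options.fix_first_stage,
            "overrides": options.overrides or {},
            "backend": "scipy-highs",
        },
    )


# ---------------------------------------------------------------------------
# independent bisection + enumeration oracle
# ---------------------------------------------------------------------------


def _oracle_feasible(
    instance: ProblemInstance,
    realization: ParameterRealization,
    lam: float,
    fixed_QT: Optional[Dict[int, float]],
    pattern_cache: Dict[str, tuple],
) -> bool:
    """Feasibility of the sub-model at a fixed lambda, by enumerating every
    indicator pattern and solving the induced plain LP with HiGHS."""
    lakes = instance.lakes
    H = [s.scenario_id for s in instance.scenarios]
    probs = {s.scenario_id: s.probability for s in instance.scenarios}
    sys_ = instance.system

    # variable order: QT per lake, then per (i,h): QS, QID, QND, QFD, FA_j
    idx: Dict[tuple, int] = {}
    pos = 0
    for lake in lakes:
        idx[("QT", lake.lake_id)] = pos
        pos += 1
    for lake in lakes:
        for h in H:
            i = lake.lake_id
            for nm in ("QS", "QID", "QND", "QFD"):
                idx[(nm, i, h)] = pos
                pos += 1
            for r in lake.regions:
                idx[("FA", i, r.region_id, h)] = pos
                pos += 1
    nvar = pos

    bounds = [(0.0, None)] * nvar
    for lake in lakes:
        i = lake.lake_id
        if fixed_QT is not None and i in fixed_QT:
            bounds[idx[("QT", i)]] = (fixed_QT[i], fixed_QT[i])
        else:
            flood = max(realization.QTF.get((lake.intake_id, h), 0.0) for h in H)
            bounds[idx[("QT", i)]] = (
                0.0, realization.QI[i] + realization.QN[i] + flood
            )

    A_ub: List[np.ndarray] = []
    b_ub: List[float] = []
    A_eq: List[np.ndarray] = []
    b_eq: List[float] = []

    def row() -> np.ndarray:
        return np.zeros(nvar)

    def le(r: np.ndarray, rhs: float) -> None:
        A_ub.append(r)
        b_ub.append(rhs)

    def ge(r: np.ndarray, rhs: float) -> None:
        A_ub.append(-r)
        b_ub.append(-rhs)

    def eq(r: np.ndarray, rhs: float) -> None:
        A_eq.append(r)
        b_eq.append(rhs)

    # habitat-area target
    r0 = row()
    for lake in lakes:
        i = lake.lake_id
        r0[idx[("QT", i)]] = realization.C[i]
        for h in H:
            r0[idx[("QS", i, h)]] = -probs[h] * realization.C[i]
    ge(r0, relaxed_requirement(
        FuzzyBound(sys_.habitat_target.lower, sys_.habitat_target.upper), lam
    ))

    for lake in lakes:
        i = lake.lake_id
        regs = sorted(lake.regions, key=lambda r: r.region_id)
        for h in H:
            # minimum demand
            r = row()
            r[idx[("QT", i)]] = 1.0
            r[idx[("QS", i, h)]] = -1.0
            ge(r, sum(
                realization.QR[i, rr.region_id]
                * relaxed_requirement(rr.area_min, lam)
                for rr in regs
            ))
            # supply balance
            r = row()
            r[idx[("QT", i)]] = 1.0
            r[idx[("QS", i, h)]] = -1.0
            for nm in ("QID", "QND", "QFD"):
                r[idx[(nm, i, h)]] = -1.0
            le(r, -realization.QL[i])
            # caps and shortage bound
            r = row(); r[idx[("QID", i, h)]] = 1.0; le(r, realization.QI[i])
            r = row(); r[idx[("QND", i, h)]] = 1.0; le(r, realization.QN[i])
            r = row(); r[idx[("QS", i, h)]] = 1.0; r[idx[("QT", i)]] = -1.0; le(r, 0.0)
            # areas
            r = row()
            for rr in regs:
                r[idx[("FA", i, rr.region_id, h)]] = 1.0
            le(r, relaxed_capacity(lake.total_planning_area, lam))
            for rr in regs:
                r = row()
                r[idx[("FA", i, rr.region_id, h)]] = 1.0
                le(r, relaxed_capacity(rr.area_max, lam))
            r = row()
            for rr in regs:
                r[idx[("FA", i, rr.region_id, h)]] = 1.0
            r[idx[("QT", i)]] = -realization.C[i]
            r[idx[("QS", i, h)]] = realization.C[i]
            ge(r, 0.0)
            r = row()
            for rr in regs:
                r[idx[("FA", i, rr.region_id, h)]] = realization.QR[i, rr.region_id]
            r[idx[("QT", i)]] = -1.0
            r[idx[("QS", i, h)]] = 1.0
            eq(r, 0.0)
            # carbon floor
            r = row()
            for rr in regs:
                r[idx[("FA", i, rr.region_id, h)]] = (
                    rr.exists * realization.NCSA[i, rr.region_id]
                )
            ge(r, realization.TCS[i])

    for n in instance.intakes:
        group = intake_group(instance, n)
        for h in H:
            r = row()
            for i in group:
                r[idx[("QFD", i, h)]] = 1.0
            le(r, realization.QTF[n, h])

    for k in sys_.service_functions:
        for h in H:
            r = row()
            for lake in lakes:
                for rr in lake.regions:
                    r[idx[("FA", lake.lake_id, rr.region_id, h)]] = (
                        rr.exists * realization.ESV.get((rr.region_id, k), 0.0)
                    )
            ge(r, realization.TEB[k])

    base_ub = np.array(A_ub) if A_ub else np.zeros((0, nvar))
    base_bub = np.array(b_ub)
    base_eq = np.array(A_eq) if A_eq else np.zeros((0, nvar))
    base_beq = np.array(b_eq)

    # (i, h) cells that carry priority indicators
    cells = []
    for lake in lakes:
        regs = {r.region_id: r for r in lake.regions}
        has_ponds = any(j in regs for j in POND_REGIONS) and any(
            j in regs for j in (REED_REGION, MARSH_REGION)
        )
        has_reed = REED_REGION in regs and MARSH_REGION in regs
        for h in H:
            cells.append((lake.lake_id, h, has_ponds, has_reed))

    def pattern_rows(pattern: Tuple[Tuple[int, int], ...]):
        ub_rows, ub_rhs, eq_rows, eq_rhs = [], [], [], []
        for (i, h, has_ponds, has_reed), (dd1, dd2) in zip(cells, pattern):
            lake = instance.lake(i)
            regs = sorted(lake.regions, key=lambda r: r.region_id)
            if has_ponds:
                pond_req = sum(
                    relaxed_requirement(rr.area_min, lam)
                    for rr in regs
                    if rr.region_id in POND_REGIONS
                )
                r = row()
                for rr in regs:
                    if rr.region_id in POND_REGIONS:
                        r[idx[("FA", i, rr.region_id, h)]] = 1.0
                if dd1 == 1:
                    ub_rows.append(-r)
                    ub_rhs.append(-pond_req)
                    r2 = row()
                    for rr in regs:
                        r2[idx[("FA", i, rr.region_id, h)]] = (
                            realization.QR[i, rr.region_id]
                        )
                    for nm in ("QID", "QND", "QFD"):
                        r2[idx[(nm, i, h)]] = -1.0
                    eq_rows.append(r2)
                    eq_rhs.append(-realization.QL[i])
                else:
                    ub_rows.append(r)
                    ub_rhs.append(pond_req)
                    r2 = row()
                    for rr in regs:
                        if rr.region_id not in POND_REGIONS:
                            r2[idx[("FA", i, rr.region_id, h)]] = (
                                realization.QR[i, rr.region_id]
                            )
                    ub_rows.append(r2)
                    ub_rhs.append(0.0)
            if has_reed:
                reed_req = relaxed_requirement(
                    lake.region(REED_REGION).area_min, lam
                )
                r = row()
                r[idx[("FA", i, REED_REGION, h)]] = 1.0
                if dd2 == 1:
                    ub_rows.append(-r)
                    ub_rhs.append(-reed_req)
                else:
                    ub_rows.append(r)
                    ub_rhs.append(reed_req)
                    r2 = row()
                    r2[idx[("FA", i, MARSH_REGION, h)]] = (
                        realization.QR[i, MARSH_REGION]
                    )
                    ub_rows.append(r2)
                    ub_rhs.append(0.0)
        return ub_rows, ub_rhs, eq_rows, eq_rhs

    def lp_feasible(pattern) -> bool:
        ub_rows, ub_rhs, eq_rows, eq_rhs = pattern_rows(pattern)
        A1 = np.vstack([base_ub] + [np.atleast_2d(r) for r in ub_rows]) if ub_rows else base_ub
        b1 = np.concatenate([base_bub, np.array(ub_rhs)]) if ub_rhs else base_bub
        A2 = np.vstack([base_eq] + [np.atleast_2d(r) for r in eq_rows]) if eq_rows else base_eq
        b2 = np.concatenate([base_beq, np.array(eq_rhs)]) if eq_rhs else base_beq
        res = linprog(
            c=np.zeros(nvar), A_ub=A1, b_ub=b1, A_eq=A2, b_eq=b2,
            bounds=bounds, method="highs",
        )
        return res.status == 0

    # try the pattern that worked last (feasibility persists along the
    # bisection most of the time), then all patterns, most-ones first
    all_patterns = sorted(
        itertools.product(itertools.product((0, 1), repeat=2), repeat=len(cells)),
        key=lambda p: -sum(a + b for a, b in p),
    )
    cached = pattern_cache.get("last")
    if cached is not None and lp_feasible(cached):
        return True
    for pattern in all_patterns:
        if pattern == cached:
            continue
        if lp_feasible(pattern):
            pattern_cache["last"] = pattern
            return True
    return False


def bisection_oracle(
    instance: ProblemInstance,
    which: str,
    grid_tol: float = 1e-4,
    fixed_QT: Optional[Dict[int, float]] = None,
    overrides: Optional[Dict[str, str]] = None,
    max_binaries: int = 12,
) -> float:
    """Largest feasible membership level, found independently of the MILP.

    Feasibility in lambda is a threshold property (every fuzzified
    requirement tightens and every fuzzified capacity shrinks as lambda
    grows), so bisection on [0, 1] with an exhaustive indicator-pattern
    enumeration at each probe certifies the optimum to ``grid_tol``.
    Refuses instances with more than ``max_binaries`` indicator binaries.
    """
    n_bin = 2 * len(instance.lakes) * len(instance.scenarios)
    if n_bin > max_binaries:
        raise ValueError(
            f"instance has {n_bin} indicator binaries; oracle cap is {max_binaries}"
        )
    if fixed_QT is None:
        fixed_QT = instance.fixed_first_stage
    realization = realize_parameters(instance, which, overrides)
    cache: Dict[str, tuple] = {}

    def feasible(lam: float) -> bool:
        return _oracle_feasible(instance, realization, lam, fixed_QT, cache)

    if not feasible(0.0):
        raise InfeasibleSubmodelError(which, ["infeasible at lambda = 0"])
    if feasible(1.0):
        return 1.0
    lo, hi = 0.0, 1.0
    while hi - lo > grid_tol:
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            lo = mid
        else:
            hi = mid
    return lo


# ---------------------------------------------------------------------------
# verification
# ---------------------------------------------------------------------------


@dataclass
class VerificationReport:
    per_run: Dict[str, Dict[str, float]]  # run -> family -> max violation
    tol: float

    @property
    def max_residual(self) -> float:
        return max(
            (v for fam in self.per_run.values() for v in fam.values()), default=0.0
        )

    @property
    def passed(self) -> bool:
        return self.max_residual <= self.tol

    def violations(self) -> Dict[str, Dict[str, float]]:
        return {
            run: {f: v for f, v in fams.items() if v > self.tol}
            for run, fams in self.per_run.items()
            if any(v > self.tol for v in fams.values())
        }


def _run_residuals(
    instance: ProblemInstance, sol: SubmodelSolution, overrides=None
) -> Dict[str, float]:
    realization = realize_parameters(instance, sol.which, overrides)
    sub = build_submodel(instance, realization, fixed_QT=sol.QT)
    x = np.zeros(sub.model.n_vars)
    x[sub.lam] = sol.lam_opt
    for i, j in sub.QT.items():
        x[j] = sol.QT[i]
    for store, vmap in (
        (sol.QS, sub.QS), (sol.QID, sub.QID), (sol.QND, sub.QND),
        (sol.QFD, sub.QFD), (sol.FA, sub.FA), (sol.d1, sub.d1), (sol.d2, sub.d2),
    ):
        for key, j in vmap.items():
            x[j] = store[key]
    return sub.model.residuals(x)


def verify_solution(
    instance: ProblemInstance,
    solution: IpftspSolution,
    tol: float = 1e-6,
    overrides: Optional[Dict[str, str]] = None,
) -> VerificationReport:
    """Re-evaluate every constraint of both runs at the reported solution."""
    per_run = {
        sol.which: _run_residuals(instance, sol, overrides)
        for sol in (solution.lower, solution.upper)
    }
    return VerificationReport(per_run=per_run, tol=tol)


# ---------------------------------------------------------------------------
# solution serialization
# ---------------------------------------------------------------------------


def _keyed(d: Dict[tuple, float] | Dict[int, float]) -> Dict[str, float]:
    out = {}
    for k, v in d.items():
        key = ",".join(map(str, k)) if isinstance(k, tuple) else str(k)
        out[key] = v
    return out


def _unkeyed(d: Dict[str, float], arity: int):
    out = {}
    for k, v in d.items():
        parts = tuple(int(p) for p in k.split(","))
        out[parts if arity > 1 else parts[0]] = v
    return out


def _sub_to_dict(sol: SubmodelSolution) -> Dict[str, object]:
    return {
        "which": sol.which,
        "lam_opt": sol.lam_opt,
        "status": sol.status,
        "QT": _keyed(sol.QT),
        "QS": _keyed(sol.QS),
        "QID": _keyed(sol.QID),
        "QND": _keyed(sol.QND),
        "QFD": _keyed(sol.QFD),
        "FA": _keyed(sol.FA),
        "d1": _keyed(sol.d1),
        "d2": _keyed(sol.d2),
        "residuals": sol.residuals,
    }


def _sub_from_dict(d: Dict[str, object]) -> SubmodelSolution:
    return SubmodelSolution(
        which=d["which"],
        lam_opt=float(d["lam_opt"]),
        status=d.get("status", "optimal"),
        QT=_unkeyed(d["QT"], 1),
        QS=_unkeyed(d["QS"], 2),
        QID=_unkeyed(d["QID"], 2),
        QND=_unkeyed(d["QND"], 2),
        QFD=_unkeyed(d["QFD"], 2),
        FA=_unkeyed(d["FA"], 3),
        d1={k: int(v) for k, v in _unkeyed(d["d1"], 2).items()},
        d2={k: int(v) for k, v in _unkeyed(d["d2"], 2).items()},
        residuals=dict(d.get("residuals", {})),
    )


def solution_to_json(solution: IpftspSolution) -> str:
    doc = {
        "lam": [solution.lam.lower, solution.lam.upper],
        "Q": {",".join(map(str, k)): [v.lower, v.upper] for k, v in solution.Q.items()},
        "lower": _sub_to_dict(solution.lower),
        "upper": _sub_to_dict(solution.upper),
        "provenance": solution.provenance,
    }
    return json.dumps(doc, indent=2) + "\n"


def solution_from_json(text: str) -> IpftspSolution:
    doc = json.loads(text)
    return IpftspSolution(
        lower=_sub_from_dict(doc["lower"]),
        upper=_sub_from_dict(doc["upper"]),
        lam=IntervalValue(*doc["lam"]),
        Q={
            tuple(int(p) for p in k.split(",")): IntervalValue(*v)
            for k, v in doc["Q"].items()
        },
        provenance=doc.get("provenance", {}),
    )


def save_solution(solution: IpftspSolution, path: str | Path) -> None:
    Path(path).write_text(solution_to_json(solution))


def load_solution(path: str | Path) -> IpftspSolution:
    return solution_from_json(Path(path).read_text())
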