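"""Minimal mixed-integer linear model container.

Thin internal layer that collects named variables and linear constraints,
compiles them to sparse matrices for ``scipy.optimize.milp`` (HiGHS) and
can serialize the model in the plain-text CPLEX-LP dialect for inspection
with any external solver.  Constraints carry a family tag so that
residual reports can aggregate by constraint family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

__all__ = ["LinearModel", "LinearSolution", "SolverFailure"]

_INF = math.inf


class SolverFailure(RuntimeError):
    """The backend terminated without a usable solution."""

    def __init__(self, message: str, status: int | None = None):
        super().__init__(message)
        self.status = status


@dataclass
class _Constraint:
    name: str
    family: str
    coeffs: Dict[int, float]
    lb: float
    ub: float


@dataclass
class LinearSolution:
    x: np.ndarray
    objective: float
    status: int
    message: str

    @property
    def feasible(self) -> bool:
        return self.status == 0


@dataclass
class LinearModel:
    maximize: bool = True
    var_names: List[str] = field(default_factory=list)
    lb: List[float] = field(default_factory=list)
    ub: List[float] = field(default_factory=list)
    integer: List[bool] = field(default_factory=list)
    objective: Dict[int, float] = field(default_factory=dict)
    constraints: List[_Constraint] = field(default_factory=list)

    # -- building -------------------------------------------------------------
    def add_var(
        self,
        name: str,
        lb: float = 0.0,
        ub: float = _INF,
        integer: bool = False,
    ) -> int:
        self.var_names.append(name)
        self.lb.append(lb)
        self.ub.append(ub)
        self.integer.append(integer)
        return len(self.var_names) - 1

    @property
    def n_vars(self) -> int:
        return len(self.var_names)

    @property
    def n_binaries(self) -> int:
        return sum(self.integer)

    def set_var_bounds(self, idx: int, lb: float, ub: float) -> None:
        self.lb[idx] = lb
        self.ub[idx] = ub

    def set_objective(self, coeffs: Dict[int, float], maximize: bool = True) -> None:
        self.objective = dict(coeffs)
        self.maximize = maximize

    def add_constraint(
        self,
        name: str,
        coeffs: Dict[int, float],
        sense: str,
        rhs: float,
        family: Optional[str] = None,
    ) -> None:
        """Add ``sum(c_j x_j) <sense> rhs`` with sense in {"<=", ">=", "=="}."""
        if sense == "<=":
            lb, ub = -_INF, rhs
        elif sense == ">=":
            lb, ub = rhs, _INF
        elif sense == "==":
            lb = ub = rhs
        else:
            raise ValueError(f"unknown sense {sense!r}")
        self.constraints.append(
            _Constraint(name, family or name.split("[")[0], dict(coeffs), lb, ub)
        )

    # -- solving --------------------------------------------------------------
    def _matrices(self) -> Tuple[sparse.csr_matrix, np.ndarray, np.ndarray]:
        rows, cols, vals = [], [], []
        lo = np.empty(len(self.constraints))
        hi = np.empty(len(self.constraints))
        for r, con in enumerate(self.constraints):
            lo[r], hi[r] = con.lb, con.ub
            for c, v in con.coeffs.items():
                if v != 0.0:
                    rows.append(r)
                    cols.append(c)
                    vals.append(v)
        A = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.constraints), self.n_vars)
        )
        return A, lo, hi

    def solve(self, mip_rel_gap: float = 0.0) -> LinearSolution:
        """Solve with HiGHS; deterministic (single solve path, no threads)."""
        c = np.zeros(self.n_vars)
        for j, v in self.objective.items():
            c[j] = v
        sign = -1.0 if self.maximize else 1.0
        A, lo, hi = self._matrices()
        res = milp(
            c=sign * c,
            constraints=LinearConstraint(A, lo, hi),
            integrality=np.array(self.integer, dtype=int),
            bounds=Bounds(np.array(self.lb), np.array(self.ub)),
            options={"mip_rel_gap": mip_rel_gap, "presolve": True},
        )
        if res.status == 2:  # infeasible
            return LinearSolution(
                x=np.full(self.n_vars, np.nan),
                objective=math.nan,
                status=2,
                message=res.message,
            )
        if res.status != 0 or res.x is None:
            raise SolverFailure(f"solver failed: {res.message}", status=res.status)
        return LinearSolution(
            x=np.asarray(res.x, dtype=float),
            objective=sign * res.fun,
            status=0,
            message=res.message,
        )

    # -- diagnostics ----------------------------------------------------------
    def residuals(self, x: np.ndarray) -> Dict[str, float]:
        """Max constraint violation per family at point ``x`` (0 if satisfied)."""
        out: Dict[str, float] = {}
        for con in self.constraints:
            val = sum(v * x[j] for j, v in con.coeffs.items())
            viol = max(con.lb - val, val - con.ub, 0.0)
            out[con.family] = max(out.get(con.family, 0.0), viol)
        for j in range(self.n_vars):
            viol = max(self.lb[j] - x[j], x[j] - self.ub[j], 0.0)
            out["bounds"] = max(out.get("bounds", 0.0), viol)
        return out

    def drop_family(self, family: str) -> "LinearModel":
        """Copy of the model without one constraint family (for diagnosis)."""
        clone = LinearModel(
            maximize=self.maximize,
            var_names=list(self.var_names),
            lb=list(self.lb),
            ub=list(self.ub),
            integer=list(self.integer),
            objective=dict(self.objective),
            constraints=[c for c in self.constraints if c.family != family],
        )
        return clone

    # -- export ---------------------------------------------------------------
    def to_lp_string(self) -> str:
        """Serialize in the CPLEX-LP text dialect."""

        def clean(name: str) -> str:
            return name.replace("[", "(").replace("]", ")").replace(",", "_")

        def term(coef: float, j: int) -> str:
            sign = "+" if coef >= 0 else "-"
            return f"{sign} {abs(coef):.12g} {clean(self.var_names[j])}"

        lines = ["Maximize" if self.maximize else "Minimize"]
        obj_terms = [term(v, j) for j, v in sorted(self.objective.items()) if v != 0.0]
        lines.append(" obj: " + (" ".join(obj_terms) or "0"))
        lines.append("Subject To")
        for idx, con in enumerate(self.constraints):
            expr = " ".join(term(v, j) for j, v in sorted(con.coeffs.items()) if v != 0.0)
            cname = clean(con.name) or f"c{idx}"
            if con.lb == con.ub:
                lines.append(f" {cname}: {expr} = {con.lb:.12g}")
            elif con.ub < _INF and con.lb == -_INF:
                lines.append(f" {cname}: {expr} <= {con.ub:.12g}")
            elif con.lb > -_INF and con.ub == _INF:
                lines.append(f" {cname}: {expr} >= {con.lb:.12g}")
            else:  # ranged: emit as two rows
                lines.append(f" {cname}_lo: {expr} >= {con.lb:.12g}")
                lines.append(f" {cname}_hi: {expr} <= {con.ub:.12g}")
        lines.append("Bounds")
        for j, name in enumerate(self.var_names):
            lo, hi = self.lb[j], self.ub[j]
            if lo == hi:
                lines.append(f" {clean(name)} = {lo:.12g}")
            elif hi == _INF:
                lines.append(f" {lo:.12g} <= {clean(name)} <= +inf")
            else:
                lines.append(f" {lo:.12g} <= {clean(name)} <= {hi:.12g}")
        binaries = [clean(self.var_names[j]) for j in range(self.n_vars) if self.integer[j]]
        if binaries:
            lines.append("Binaries")
            lines.append(" " + " ".join(binaries))
        lines.append("End")
        return "\n".join(lines) + "\n"
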