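# Methods

## The planning model

The package plans ecological water supplement for a wetland reserve: a set
of lakes *i = 1..I*, each fed from one of *N* water intakes and divided
into ecological function regions *j* (1 fish pond, 2 crab pond, 3 reed
wetland, 4 marsh wetland).  Flood inflow is a discrete random variable
with scenarios *h* of probability *P_h*.  Decisions are two-staged:
first-stage water-supply targets *QT_i* are fixed before the flood
scenario is known; second-stage shortages *QS_ih >= 0* adapt afterwards.
The net supplement *QT_i − QS_ih* converts to restored area through the
per-area water demands *QR_ij* and to suitable bird habitat through a
habitat-per-water coefficient *C_i* (the habitat is the 0–40 cm-deep water
area usable by the cranes and storks the reserve protects).

Uncertainty enters three ways:

* **interval coefficients** (*C, QR, supplies, losses, benefit rates and
  floors*) are known only as `[lower, upper]` ranges;
* **scenario randomness** in the flood resource *QTF_nh* available per
  intake;
* **fuzzy flexibility** in the area bounds: the minimum and maximum region
  areas and each lake's total planning area are semi-trapezoidal fuzzy
  bounds `(b, a)` whose membership rises linearly from 0 at `b` to 1 at
  `a`.

The objective is **max λ**, the scalar membership level in [0, 1] at
which every fuzzified constraint is satisfied: requirements harden from
`b` to `a` as `a − (1−λ)(a−b)` and capacities shrink from `a` to `b` as
`b + (1−λ)(a−b)`.  λ measures how fully the flexible targets are met and
proxies the decision risk the planner accepts.  The constraint set is:

* habitat target: `Σ_i C_i QT_i − Σ_i Σ_h P_h C_i QS_ih >= f⁻ + λ (f⁺ − f⁻)`
  with `(f⁻, f⁺)` the habitat-area interval of the antecedent
  interval-parameter model, consumed as input;
* minimum water demand per lake/scenario at the fuzzified minimum areas;
* water balance: net supplement ≤ local + normal + flood deliveries − loss,
  with per-lake caps *QI, QN*, per-intake flood caps *QTF_nh*, and
  `QS_ih <= QT_i` (the shortage cannot exceed the target — implicit in the
  formulation, added explicitly here);
* supplement priority: ponds (j = 1, 2) are served before reed and marsh,
  and reed before marsh — conditional constraints, see below;
* area constraints: region areas within their fuzzified boxes, lake totals
  within the fuzzified planning area, total area at least the habitat
  area, and the exact conversion `Σ_j FA_ijh QR_ij = QT_i − QS_ih`;
* benefit floors: ecosystem-service value per service function *k*
  (`Σ FA·Y·ESV_jk >= TEB_k`) and net carbon sink per lake
  (`Σ FA·Y·NCSA_ij >= TCS_i`), with *Y_ij* a fixed 0/1 existence
  indicator supplied as data.

## Interactive two-run solution

Interval coefficients are resolved by the standard interactive two-step
scheme: every parameter is fixed at its *favorable* endpoint (more
habitat per unit water, lower demand, higher caps, lower loss, easier
floors) to form the **upper run**, and at the opposite endpoints for the
**lower run**.  The upper run is solved first with *QT* free and fixes
the crisp first-stage targets; the lower run re-solves with *QT* pinned
to those targets (an option allows *QT* free in both).  The two optima
form the reported intervals, always combined by sort-after-pairing —
derived ratios such as the flood share can invert the run ordering, so
positional assignment would be wrong.

Because the habitat coefficient multiplies both the first-stage and the
recourse term of the habitat constraint, a strict sign-aware endpoint
assignment is ambiguous for it; the package uses uniform per-parameter
favorable/adverse endpoints, and the map is user-overridable per family
(`realize_parameters(..., overrides=...)`).

### Priority conditionals and big-M linearization

The pond-priority rule is an if/else: if the pond areas reach their
fuzzified minimum, the delivered water must be fully converted to area
(making the supply balance tight); otherwise reed and marsh receive no
water.  Each (lake, scenario) cell gets two binaries (ponds reached
minimum; reed reached minimum) linked through big-M inequality pairs.
The per-lake M is certified: the largest per-area demand times the
loosest planning area, plus all supply capacities and the loss, bounds
every linear expression in the block.  Ties at the threshold resolve to
the "requirement met" branch.  The reed/marsh rule's if-branch
(`FA_4·QR_4 = Σ_{j=3,4} FA_j·QR_j − FA_3·QR_3`) is an algebraic identity
and emits nothing; only the indicator link and the else-branch
(`FA_4 = 0`) are materialized.

### Lexicographic tie-break

"Max λ" leaves the continuous variables massively degenerate: targets can
be inflated arbitrarily (shortages absorb the excess), deliveries can
exceed need wherever the balance is slack, and the area split between
regions is free once the net water is fixed.  Two design choices make
solutions unique and reproducible:

1. an explicit deliverability bound `QT_i <= QI_i + QN_i + max_h QTF`
   (targets beyond any deliverable volume are meaningless);
2. after the MILP fixes λ and the indicator pattern, a second LP
   re-optimizes the continuous variables: maximize the expected net
   supplement, then (at vanishing weights, 1e-4 of a volume unit)
   minimize shortages and deliveries with flood water preferred over
   local over normal supply — mirroring the flood-first utilization the
   plan is designed around — and pin the area split with a
   region-ordered vanishing cost (1e-6).

The tie-break weights are separated from the primary objective by several
orders of magnitude, so they select among λ-optimal points without
perturbing λ (the oracle agreement test bounds any such perturbation by
1e-4).

### Backend

Both phases run on HiGHS through `scipy.optimize.milp` / `linprog`
(single deterministic solve path; repeated runs are bit-identical).
Feasibility tolerances are HiGHS defaults (1e-7 primal); verification
re-evaluates every constraint family at the reported point and requires
residuals ≤ 1e-6.  Sub-models can be exported in the CPLEX-LP text
dialect for inspection with any external solver.

## Independent oracle

Feasibility in λ is a threshold property: every fuzzified requirement is
nondecreasing and every fuzzified capacity nonincreasing in λ, and a
point feasible at λ₂ can be repaired into a feasible point at any
λ₁ < λ₂ (deliveries are reduced to re-tighten the full-use branch).  The
oracle exploits this: it bisects λ on [0, 1] and, at each probe, tests
feasibility by enumerating *all* indicator patterns and solving the
induced plain LPs — no big-M, no MILP, a fully independent code path.
It refuses instances with more than 12 indicator binaries (the
enumeration is exponential), which bounds it to about 2 lakes x 2–3
scenarios; agreement with the MILP within 1e-4 is an acceptance
property.

## Synthetic instances

The published case study (18 lakes under 4 intakes, four function
regions, scenarios with probabilities 0.50/0.38/0.12) prints its results
but not its per-lake parameter tables, so instances with that structure
are synthesized.  The generator is *construction-by-feasibility*:

1. draw candidate areas FA\* inside the fuzzy boxes evaluated at a target
   membership λ\* (default 0.5): above the fuzzified minima by 2–10 %,
   with maxima 1.6–1.8x above the candidate;
2. price the candidate in water at the adverse demand endpoints;
3. size local + normal supply so that they *alone* cover the adverse
   candidate demand with an 8 % margin — no lake can then be starved by
   the shared flood resource, whatever allocation the LP picks;
4. set per-intake flood availability as a rising fraction of the adverse
   group demand across scenarios (defaults 0.22/0.38/0.58), so delivery
   binds under low flood and the area boxes bind under high flood;
5. set benefit floors at 85 % of the candidate's adverse-endpoint
   benefits;
6. bracket the habitat target so the requirement at λ\* stays below 96 %
   of the candidate habitat (feasibility), while f⁺ sits 5 % above a
   fractional-knapsack upper bound on the favorable run's reachable
   habitat (so the target binds and λ⁺ < 1).

This guarantees the adverse run is feasible at λ\*, hence λ⁻ ≥ λ\* after
the two-step solve — a property the test suite verifies rather than
assumes.  Scales are chosen to match the magnitudes of the published
study: per-area demands 400–900 x10^4 m^3 per 10^3 ha (reed above the
ponds, marsh lowest), habitat coefficients ~8e-4 x10^3 ha per 10^4 m^3,
service values ~10^2 x10^6 CNY per 10^3 ha (ponds above wetlands), carbon
sinks ~10^3 t per 10^3 ha (wetlands above ponds), 34.23 x10^3 ha of
total planning area.  All draws are uniform on configured ranges (no
distributional information exists to justify anything sharper) from a
seeded PCG64 generator; the seed is recorded in the instance metadata and
identical seeds give byte-identical files.

What the generator does **not** emulate: real hydrology (no correlation
between scenario probability and flood volume beyond monotonicity), the
actual unpublished parameter tables, water-level–area–volume geometry
(the habitat coefficient is consumed as an input, as in the model), or
spatial structure.  Passing tests therefore demonstrate the *solver and
accounting machinery* on structurally faithful instances, not a
recovery of the original study's numbers — those enter only the
accounting layer, whose fixture tables are the study's printed results.

The case-study skeleton (`mnnr_skeleton`) overlays everything the study
prints — groupings, probabilities, per-intake first-stage targets
(spread over lakes proportionally to synthetic supply capacity), the
habitat target interval (14.53, 19.28) x10^3 ha, the 0.76 ha/bird
density, recommended-scheme and antecedent-model references — on a
fixed-seed synthetic fill, flagged as synthetic in the file metadata.

## Numerical choices and conventions

* Units are fixed by the schema (10^4 m^3, 10^3 ha, 10^6 CNY, t) and
  never converted inside the solver.
* Percent-style quantities are fractions internally; formatting rounds
  half-up to two decimals only at the reporting boundary.  When printed
  tables are used as fixtures, comparisons allow one unit in the last
  printed digit (the source tables themselves carry 0.01-level drift
  between entries computed from unrounded internals).
* Degenerate inputs: a fuzzy bound with `a = b` behaves as a crisp value
  (step membership; both relaxations return it unchanged), and crisp
  intervals make the two runs identical, so a pure-LP crisp instance
  flows through the full machinery.
* Accounting identity: `target = shortage + (actual supply − conveyance
  loss)` per lake, scenario and run; the printed fixture tables have zero
  loss, so there it reduces to `target = shortage + actual`.
* Infeasibility diagnosis relaxes constraint families softest-first
  (service-value floors, carbon floors, minimum demand, habitat target)
  and reports which removals restore feasibility.
* Problem sizes in the test-suite: closed-form single-region toys,
  twenty 2-lake/2-scenario instances for oracle agreement, and
  18-lake/3-scenario instances for the structural checks — the full
  case-study size, solved in well under a second per run.

## Known limitations

* The oracle's pattern enumeration is exponential; it is a verification
  device for small instances, never a solution path.
* The priority conditionals assume positive per-area demands; a region
  with zero demand would make its else-branch vacuous.
* λ is a single system-wide membership level; per-constraint membership
  targets are not modeled.
* The antecedent interval model that produces the habitat target interval
  and the comparison references is consumed as input, not reimplemented.
* Bird carrying capacity divides habitat area by a single fixed density
  (default 0.76 ha/bird); species-specific or seasonal densities are out
  of scope.
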