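"""Declarative problem instances for the water-allocation model.

An instance describes a nature reserve as a set of lakes, each fed from one
water intake and partitioned into ecological function regions (fish pond,
crab pond, reed wetland, marsh wetland), together with a finite set of
flood-flow scenarios with probabilities, interval-valued coefficients,
fuzzy (flexible) area bounds and benefit floors.

Serialization: a single JSON document with sections
``{meta, system, intakes, lakes, scenarios}``.  Intervals serialize as
``[lower, upper]``, fuzzy bounds as ``{"b": ..., "a": ...}``.  All ids are
explicit and 1-based; nothing is positional.  A CSV bundle importer
(``lakes.csv``, ``regions.csv``, ``scenarios.csv``, ``esv.csv`` plus an
optional ``system.json``) maps onto the same model.

Units are fixed by the schema and never converted inside the solver:
volumes in 10^4 m^3, areas in 10^3 ha, per-area water demand in
10^4 m^3 / 10^3 ha, ecosystem-service values in 10^6 CNY, carbon in t.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Annotated, Any, Dict, List, Optional

import pandas as pd
from pydantic import BaseModel, BeforeValidator, ConfigDict, Field, PlainSerializer

from .fuzzy import FuzzyBound, IntervalValue

__all__ = [
    "Interval",
    "Fuzzy",
    "FunctionRegionSpec",
    "LakeSpec",
    "ScenarioSpec",
    "ReferenceScheme",
    "IptspReference",
    "SystemSpec",
    "ProblemInstance",
    "validate_instance",
    "intake_group",
    "instance_to_json",
    "instance_from_json",
    "load_instance",
    "save_instance",
    "load_csv_bundle",
    "instance_hash",
]


def _as_interval(v: Any) -> IntervalValue:
    if isinstance(v, IntervalValue):
        return v
    if isinstance(v, (list, tuple)) and len(v) == 2:
        return IntervalValue(float(v[0]), float(v[1]))
    if isinstance(v, dict) and {"lower", "upper"} <= set(v):
        return IntervalValue(float(v["lower"]), float(v["upper"]))
    if isinstance(v, (int, float)):
        return IntervalValue.crisp(float(v))
    raise TypeError(f"cannot interpret {v!r} as an interval")


def _as_fuzzy(v: Any) -> FuzzyBound:
    if isinstance(v, FuzzyBound):
        return v
    if isinstance(v, dict) and {"b", "a"} <= set(v):
        return FuzzyBound(float(v["b"]), float(v["a"]))
    if isinstance(v, (list, tuple)) and len(v) == 2:
        return FuzzyBound(float(v[0]), float(v[1]))
    if isinstance(v, (int, float)):
        return FuzzyBound.crisp(float(v))
    raise TypeError(f"cannot interpret {v!r} as a fuzzy bound")


Interval = Annotated[
    IntervalValue,
    BeforeValidator(_as_interval),
    PlainSerializer(lambda v: [v.lower, v.upper], return_type=list),
]
Fuzzy = Annotated[
    FuzzyBound,
    BeforeValidator(_as_fuzzy),
    PlainSerializer(lambda v: {"b": v.b, "a": v.a}, return_type=dict),
]

_MODEL_CONFIG = ConfigDict(arbitrary_types_allowed=True, validate_assignment=False)


class FunctionRegionSpec(BaseModel):
    """One ecological function region of a lake (index j)."""

    model_config = _MODEL_CONFIG

    region_id: int
    water_demand_per_area: Interval  # QR, 10^4 m^3 per 10^3 ha
    area_min: Fuzzy  # fuzzy lower area boundary, 10^3 ha
    area_max: Fuzzy  # fuzzy upper area boundary, 10^3 ha
    exists: int = 1  # fixed 0/1 indicator Y
    carbon_sink_per_area: Interval = IntervalValue.crisp(0.0)  # t per 10^3 ha


class LakeSpec(BaseModel):
    """One lake (index i), assigned to exactly one intake."""

    model_config = _MODEL_CONFIG

    lake_id: int
    intake_id: int
    habitat_coefficient: Interval  # C, 10^3 ha habitat per 10^4 m^3 net water
    supply_loss: Interval = IntervalValue.crisp(0.0)  # QL, 10^4 m^3
    local_supply_cap: Interval = IntervalValue.crisp(0.0)  # QI, 10^4 m^3
    normal_supply_cap: Interval = IntervalValue.crisp(0.0)  # QN, 10^4 m^3
    total_planning_area: Fuzzy = FuzzyBound.crisp(0.0)  # TFA, 10^3 ha
    carbon_sink_floor: Interval = IntervalValue.crisp(0.0)  # TCS, t
    regions: List[FunctionRegionSpec] = Field(default_factory=list)

    def region(self, j: int) -> FunctionRegionSpec:
        for r in self.regions:
            if r.region_id == j:
                return r
        raise KeyError(f"lake {self.lake_id} has no region {j}")


class ScenarioSpec(BaseModel):
    """One flood-flow scenario (index h) with its probability."""

    model_config = _MODEL_CONFIG

    scenario_id: int
    probability: float
    flood_available: Dict[int, Interval] = Field(default_factory=dict)  # per intake


class ReferenceScheme(BaseModel):
    """Recommended-scheme reference values used by comparison reports."""

    model_config = _MODEL_CONFIG

    habitat_area: Optional[float] = None  # 10^3 ha
    region_habitat: Dict[int, float] = Field(default_factory=dict)  # per region r
    function_region_areas: Dict[int, float] = Field(default_factory=dict)  # per j
    total_area: Optional[float] = None  # 10^3 ha
    esv: Optional[float] = None  # 10^6 CNY
    carbon_sink: Optional[float] = None  # t


class IptspReference(BaseModel):
    """Result intervals of the antecedent interval-parameter model.

    Consumed purely as reference inputs for width-reduction reports; keys
    are scenario ids for per-scenario tables.
    """

    model_config = _MODEL_CONFIG

    actual_supply: Dict[int, Interval] = Field(default_factory=dict)  # 10^4 m^3
    habitat_area: Dict[int, Interval] = Field(default_factory=dict)  # 10^3 ha
    habitat_target: Optional[Interval] = None  # 10^3 ha
    total_area: Dict[int, Interval] = Field(default_factory=dict)  # 10^3 ha
    esv: Dict[int, Interval] = Field(default_factory=dict)  # 10^6 CNY
    carbon_sink: Dict[int, Interval] = Field(default_factory=dict)  # t


class SystemSpec(BaseModel):
    """System-level targets, benefit floors and reference records."""

    model_config = _MODEL_CONFIG

    habitat_target: Interval  # (f-, f+), 10^3 ha, from the antecedent model
    esv_per_area: Dict[int, Dict[int, Interval]] = Field(default_factory=dict)  # [j][k]
    esv_floor: Dict[int, Interval] = Field(default_factory=dict)  # TEB per k
    bird_density: float = 0.76  # ha per bird
    reference_scheme: Optional[ReferenceScheme] = None
    reference_iptsp: Optional[IptspReference] = None

    @property
    def service_functions(self) -> List[int]:
        return sorted(self.esv_floor)


class ProblemInstance(BaseModel):
    """The complete declarative input of one planning problem."""

    model_config = _MODEL_CONFIG

    meta: Dict[str, Any] = Field(default_factory=dict)
    system: SystemSpec
    intakes: Dict[int, str] = Field(default_factory=dict)
    lakes: List[LakeSpec] = Field(default_factory=list)
    scenarios: List[ScenarioSpec] = Field(default_factory=list)
    fixed_first_stage: Optional[Dict[int, float]] = None  # QT per lake, 10^4 m^3

    # -- convenience accessors ------------------------------------------------
    @property
    def lake_ids(self) -> List[int]:
        return [lake.lake_id for lake in self.lakes]

    @property
    def scenario_ids(self) -> List[int]:
        return [s.scenario_id for s in self.scenarios]

    @property
    def region_ids(self) -> List[int]:
        seen: List[int] = []
        for lake in self.lakes:
            for r in lake.regions:
                if r.region_id not in seen:
                    seen.append(r.region_id)
        return sorted(seen)

    def lake(self, i: int) -> LakeSpec:
        for lake in self.lakes:
            if lake.lake_id == i:
                return lake
        raise KeyError(f"no lake with id {i}")

    def scenario(self, h: int) -> ScenarioSpec:
        for s in self.scenarios:
            if s.scenario_id == h:
                return s
        raise KeyError(f"no scenario with id {h}")


def intake_group(instance: ProblemInstance, n: int) -> List[int]:
    """Lake ids served by intake ``n`` (sorted; the flood-balance grouping)."""
    if n not in instance.intakes:
        raise KeyError(f"unknown intake {n}")
    return sorted(l.lake_id for l in instance.lakes if l.intake_id == n)


def validate_instance(instance: ProblemInstance) -> List[str]:
    """Check cross-field invariants; return a list of violation messages.

    An empty list means the instance is internally consistent.  The checks
    are side-effect free and idempotent; structural/type errors are already
    rejected at parse time by the model classes.
    """
    v: List[str] = []

    if not instance.lakes:
        v.append("instance has no lakes")
    if not instance.scenarios:
        v.append("instance has no scenarios")
    if not instance.intakes:
        v.append("instance has no intakes")

    seen_lakes = set()
    for lake in instance.lakes:
        if lake.lake_id in seen_lakes:
            v.append(f"duplicate lake id {lake.lake_id}")
        seen_lakes.add(lake.lake_id)
        if lake.intake_id not in instance.intakes:
            v.append(f"lake {lake.lake_id}: references unknown intake {lake.intake_id}")
        if lake.habitat_coefficient.lower <= 0:
            v.append(f"lake {lake.lake_id}: habitat coefficient must be positive")
        for field in ("supply_loss", "local_supply_cap", "normal_supply_cap"):
            if getattr(lake, field).lower < 0:
                v.append(f"lake {lake.lake_id}: {field} must be nonnegative")
        seen_regions = set()
        for r in lake.regions:
            tag = f"lake {lake.lake_id} region {r.region_id}"
            if r.region_id in seen_regions:
                v.append(f"duplicate region id in lake {lake.lake_id}: {r.region_id}")
            seen_regions.add(r.region_id)
            if r.exists not in (0, 1):
                v.append(f"{tag}: existence indicator must be 0 or 1")
            if r.exists and r.water_demand_per_area.lower <= 0:
                v.append(f"{tag}: per-area water demand must be positive")
            if r.area_min.a > r.area_max.a or r.area_min.b > r.area_max.b:
                v.append(f"{tag}: minimum area bound exceeds maximum area bound")

    prob_sum = sum(s.probability for s in instance.scenarios)
    if instance.scenarios and abs(prob_sum - 1.0) > 1e-9:
        v.append(f"scenario probabilities sum to {prob_sum!r}, expected 1")
    seen_scenarios = set()
    for s in instance.scenarios:
        if s.scenario_id in seen_scenarios:
            v.append(f"duplicate scenario id {s.scenario_id}")
        seen_scenarios.add(s.scenario_id)
        if not (0 < s.probability <= 1):
            v.append(f"scenario {s.scenario_id}: probability must lie in (0, 1]")
        for n in instance.intakes:
            if n not in s.flood_available:
                v.append(f"scenario {s.scenario_id}: no flood availability for intake {n}")
        for n in s.flood_available:
            if n not in instance.intakes:
                v.append(f"scenario {s.scenario_id}: flood entry for unknown intake {n}")

    sys_ = instance.system
    if sys_.habitat_target.lower >= sys_.habitat_target.upper:
        v.append("habitat target interval must have positive width")
    if sys_.bird_density <= 0:
        v.append("bird density must be positive")
    region_ids = set(instance.region_ids)
    for k, floor in sys_.esv_floor.items():
        for j in region_ids:
            if j not in sys_.esv_per_area or k not in sys_.esv_per_area.get(j, {}):
                v.append(f"service function {k}: no per-area value for region {j}")
                break
        if floor.lower < 0:
            v.append(f"service function {k}: benefit floor must be nonnegative")

    if instance.fixed_first_stage is not None:
        for i in instance.fixed_first_stage:
            if i not in seen_lakes:
                v.append(f"fixed first-stage target for unknown lake {i}")

    return v


# -- serialization ------------------------------------------------------------


def instance_to_json(instance: ProblemInstance) -> str:
    """Canonical JSON text (fixed field order, 2-space indent)."""
    return json.dumps(instance.model_dump(mode="json"), indent=2) + "\n"


def instance_from_json(text: str) -> ProblemInstance:
    return ProblemInstance.model_validate(json.loads(text))


def save_instance(instance: ProblemInstance, path: str | Path) -> None:
    Path(path).write_text(instance_to_json(instance))


def load_instance(path: str | Path) -> ProblemInstance:
    return instance_from_json(Path(path).read_text())


def instance_hash(instance: ProblemInstance) -> str:
    """Stable content hash of the canonical serialization."""
    return hashlib.sha256(instance_to_json(instance).encode()).hexdigest()[:16]


def load_csv_bundle(directory: str | Path) -> ProblemInstance:
    """Assemble an instance from a directory of per-table CSV files.

    Expected files: ``lakes.csv``, ``regions.csv``, ``scenarios.csv``
    (long format, one row per scenario x intake), ``esv.csv`` (one row per
    region x service function), and an optional ``system.json`` carrying
    the habitat target interval, bird density and reference records.
    """
    d = Path(directory)
    lakes_df = pd.read_csv(d / "lakes.csv")
    regions_df = pd.read_csv(d / "regions.csv")
    scen_df = pd.read_csv(d / "scenarios.csv")
    esv_df = pd.read_csv(d / "esv.csv")

    lakes: List[LakeSpec] = []
    for _, row in lakes_df.iterrows():
        i = int(row["lake_id"])
        regs = []
        for _, rr in regions_df[regions_df["lake_id"] == i].iterrows():
            regs.append(
                FunctionRegionSpec(
                    region_id=int(rr["region_id"]),
                    water_demand_per_area=[rr["QR_lower"], rr["QR_upper"]],
                    area_min={"b": rr["Amin_b"], "a": rr["Amin_a"]},
                    area_max={"b": rr["Amax_b"], "a": rr["Amax_a"]},
                    exists=int(rr.get("Y", 1)),
                    carbon_sink_per_area=[rr["NCSA_lower"], rr["NCSA_upper"]],
                )
            )
        lakes.append(
            LakeSpec(
                lake_id=i,
                intake_id=int(row["intake_id"]),
                habitat_coefficient=[row["C_lower"], row["C_upper"]],
                supply_loss=[row["QL_lower"], row["QL_upper"]],
                local_supply_cap=[row["QI_lower"], row["QI_upper"]],
                normal_supply_cap=[row["QN_lower"], row["QN_upper"]],
                total_planning_area={"b": row["TFA_b"], "a": row["TFA_a"]},
                carbon_sink_floor=[row["TCS_lower"], row["TCS_upper"]],
                regions=regs,
            )
        )

    scenarios: List[ScenarioSpec] = []
    for h, grp in scen_df.groupby("scenario_id"):
        scenarios.append(
            ScenarioSpec(
                scenario_id=int(h),
                probability=float(grp["probability"].iloc[0]),
                flood_available={
                    int(r["intake_id"]): [r["QTF_lower"], r["QTF_upper"]]
                    for _, r in grp.iterrows()
                },
            )
        )
    scenarios.sort(key=lambda s: s.scenario_id)

    esv_per_area: Dict[int, Dict[int, IntervalValue]] = {}
    esv_floor: Dict[int, IntervalValue] = {}
    for _, row in esv_df.iterrows():
        j, k = int(row["region_id"]), int(row["service_id"])
        esv_per_area.setdefault(j, {})[k] = IntervalValue(
            float(row["ESV_lower"]), float(row["ESV_upper"])
        )
        esv_floor[k] = IntervalValue(float(row["TEB_lower"]), float(row["TEB_upper"]))

    sys_kwargs: Dict[str, Any] = {"esv_per_area": esv_per_area, "esv_floor": esv_floor}
    meta: Dict[str, Any] = {"source": "csv-bundle"}
    intakes = {int(n): f"intake-{int(n)}" for n in sorted(lakes_df["intake_id"].unique())}
    sys_path = d / "system.json"
    if sys_path.exists():
        sys_json = json.loads(sys_path.read_text())
        meta.update(sys_json.get("meta", {}))
        if "intakes" in sys_json:
            intakes = {int(n): name for n, name in sys_json["intakes"].items()}
        for key in (
            "habitat_target",
            "bird_density",
            "reference_scheme",
            "reference_iptsp",
        ):
            if key in sys_json:
                sys_kwargs[key] = sys_json[key]
    if "habitat_target" not in sys_kwargs:
        raise ValueError("CSV bundle needs system.json with a habitat_target interval")

    return ProblemInstance(
        meta=meta,
        system=SystemSpec(**sys_kwargs),
        intakes=intakes,
        lakes=sorted(lakes, key=lambda l: l.lake_id),
        scenarios=scenarios,
    )
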