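"""Domain model for costed clinical workflows.

A workflow is a process map: an ordered list of *stages* (consultation,
simulation, planning, treatment, ...) populated by *steps*.  Each step
consumes resources — personnel, equipment, or rooms — for a number of
minutes per occurrence, may involve more than one staff member
(``headcount``), may apply only to a fraction of patients
(``occurrence_prob``), and may repeat on every treatment fraction
(``per_fraction``).

Resources carry a capacity cost rate (CCR, USD per minute); if only an
annual cost and a working schedule are given, the rate is derived by the
costing engine.  Minutes and probabilities accept exact
:class:`fractions.Fraction` values so that tables back-derived from
published costs reproduce those costs without floating-point drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Union

import pandas as pd
import yaml

__all__ = [
    "CATEGORIES",
    "DEFAULT_STAGES",
    "Resource",
    "ResourceTable",
    "ResourceUsage",
    "ProcessStep",
    "Workflow",
    "SchemaError",
    "validate_workflow",
    "read_workflow",
    "write_workflow",
    "read_resources",
    "write_resources",
]

Minutes = Union[int, float, Fraction]

CATEGORIES = ("personnel", "equipment", "space")

#: The stage sequence of a generic external-beam radiotherapy course.
DEFAULT_STAGES = (
    "consultation",
    "simulation",
    "planning",
    "treatment",
    "on-treatment visit",
    "follow-up",
)


class SchemaError(ValueError):
    """A structured-text input does not conform to the documented schema.

    Distinct from validation issues: schema errors mean the file could not
    be mapped onto the data model at all; validation issues describe a
    well-formed model that violates an invariant.
    """


@dataclass(frozen=True)
class Resource:
    """A costed capacity: one personnel category, machine, or room.

    Either ``ccr`` (USD/min) or ``annual_cost`` (USD/yr, together with the
    working schedule) must be present.  When both are given they must agree
    to 0.5% relative, a guard against stale tables.
    """

    id: str
    name: str
    category: str
    annual_cost: float | None = None
    annual_days: float | None = None
    daily_hours: float | None = None
    ccr: float | None = None
    useful_life_years: float | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise SchemaError(
                f"resource {self.id!r}: category {self.category!r} not one of {CATEGORIES}"
            )

    def validate(self) -> list[str]:
        issues: list[str] = []
        if self.annual_days is not None and self.annual_days <= 0:
            issues.append(f"resource {self.id!r}: annual_days must be > 0")
        if self.daily_hours is not None and self.daily_hours <= 0:
            issues.append(f"resource {self.id!r}: daily_hours must be > 0")
        if self.annual_cost is None and self.ccr is None:
            issues.append(
                f"resource {self.id!r}: needs at least one of annual_cost, ccr"
            )
        if (
            self.annual_cost is not None
            and self.ccr is not None
            and self.annual_days
            and self.daily_hours
        ):
            derived = self.annual_cost / (self.annual_days * self.daily_hours * 60.0)
            if self.ccr and not math.isclose(derived, self.ccr, rel_tol=5e-3):
                issues.append(
                    f"resource {self.id!r}: supplied ccr {self.ccr} disagrees with "
                    f"annual_cost-derived {derived:.4f} by more than 0.5%"
                )
        return issues


class ResourceTable(Mapping[str, Resource]):
    """An id-keyed collection of :class:`Resource` rows."""

    def __init__(self, resources: Iterable[Resource]):
        self._by_id: dict[str, Resource] = {}
        for r in resources:
            if r.id in self._by_id:
                raise SchemaError(f"duplicate resource id {r.id!r}")
            self._by_id[r.id] = r

    def __getitem__(self, rid: str) -> Resource:
        return self._by_id[rid]

    def __iter__(self) -> Iterator[str]:
        return iter(self._by_id)

    def __len__(self) -> int:
        return len(self._by_id)

    def category(self, rid: str) -> str:
        return self._by_id[rid].category

    def validate(self) -> list[str]:
        return [issue for r in self._by_id.values() for issue in r.validate()]

    def scaled(self, k: float) -> "ResourceTable":
        """A copy with every cost rate multiplied by ``k`` (for sensitivity)."""
        return ResourceTable(
            replace(
                r,
                ccr=None if r.ccr is None else r.ccr * k,
                annual_cost=None if r.annual_cost is None else r.annual_cost * k,
            )
            for r in self._by_id.values()
        )


@dataclass(frozen=True)
class ResourceUsage:
    """One resource's engagement in a step: ``headcount`` people (or one
    machine/room) for ``minutes`` per occurrence."""

    resource_id: str
    minutes: Minutes
    headcount: int = 1

    def validate(self, context: str) -> list[str]:
        issues = []
        if not (isinstance(self.minutes, Fraction) or math.isfinite(self.minutes)):
            issues.append(f"{context}: usage of {self.resource_id!r}: minutes not finite")
        elif self.minutes < 0:
            issues.append(f"{context}: usage of {self.resource_id!r}: minutes < 0")
        if self.headcount < 1:
            issues.append(f"{context}: usage of {self.resource_id!r}: headcount < 1")
        return issues


@dataclass(frozen=True)
class ProcessStep:
    id: str
    label: str
    stage: str
    usages: tuple[ResourceUsage, ...] = ()
    occurrence_prob: Minutes = 1
    per_fraction: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "usages", tuple(self.usages))


@dataclass(frozen=True)
class Workflow:
    """A process map for one treatment modality."""

    modality: str
    n_fractions: int
    steps: tuple[ProcessStep, ...] = ()
    stages: tuple[str, ...] = DEFAULT_STAGES

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", tuple(self.steps))
        object.__setattr__(self, "stages", tuple(self.stages))

    def step(self, step_id: str) -> ProcessStep:
        for s in self.steps:
            if s.id == step_id:
                return s
        raise KeyError(step_id)

    def with_steps(self, steps: Iterable[ProcessStep]) -> "Workflow":
        return replace(self, steps=tuple(steps))


def validate_workflow(
    workflow: Workflow, resource_table: ResourceTable
) -> list[str]:
    """Check every model invariant; return one message per violation.

    An empty list means the workflow is internally consistent and fully
    resolvable against ``resource_table``.
    """
    issues = resource_table.validate()
    if workflow.n_fractions < 1:
        issues.append(f"workflow {workflow.modality!r}: n_fractions must be >= 1")
    seen: set[str] = set()
    for step in workflow.steps:
        ctx = f"step {step.id!r}"
        if step.id in seen:
            issues.append(f"{ctx}: duplicate step id")
        seen.add(step.id)
        if step.stage not in workflow.stages:
            issues.append(
                f"{ctx}: stage {step.stage!r} not in workflow stages {list(workflow.stages)}"
            )
        if not (0 <= step.occurrence_prob <= 1):
            issues.append(
                f"{ctx}: occurrence_prob {float(step.occurrence_prob)} outside [0, 1]"
            )
        for usage in step.usages:
            issues.extend(usage.validate(ctx))
            if usage.resource_id not in resource_table:
                issues.append(
                    f"{ctx}: usage references unknown resource {usage.resource_id!r}"
                )
            elif (
                usage.headcount > 1
                and resource_table.category(usage.resource_id) != "personnel"
            ):
                issues.append(
                    f"{ctx}: headcount > 1 on non-personnel resource {usage.resource_id!r}"
                )
    return issues


# ---------------------------------------------------------------------------
# serialization

def _num_out(x: Minutes):
    if isinstance(x, Fraction):
        if x.denominator == 1:
            return int(x)
        return f"{x.numerator}/{x.denominator}"
    return x


def _num_in(x, path: str) -> Minutes:
    if isinstance(x, bool) or x is None:
        raise SchemaError(f"{path}: expected a number, got {x!r}")
    if isinstance(x, (int, float)):
        return x
    if isinstance(x, str):
        try:
            return Fraction(x)
        except (ValueError, ZeroDivisionError) as exc:
            raise SchemaError(f"{path}: cannot parse number {x!r}") from exc
    raise SchemaError(f"{path}: expected a number, got {type(x).__name__}")


def _require(mapping: dict, key: str, path: str):
    if key not in mapping:
        raise SchemaError(f"{path}: missing required key {key!r}")
    return mapping[key]


def workflow_to_dict(workflow: Workflow) -> dict:
    return {
        "modality": workflow.modality,
        "n_fractions": workflow.n_fractions,
        "stages": list(workflow.stages),
        "steps": [
            {
                "id": s.id,
                "label": s.label,
                "stage": s.stage,
                "occurrence_prob": _num_out(s.occurrence_prob),
                "per_fraction": s.per_fraction,
                "usages": [
                    {
                        "resource": u.resource_id,
                        "headcount": u.headcount,
                        "minutes": _num_out(u.minutes),
                    }
                    for u in s.usages
                ],
            }
            for s in workflow.steps
        ],
    }


def workflow_from_dict(doc: dict, path: str = "workflow") -> Workflow:
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: expected a mapping at top level")
    modality = _require(doc, "modality", path)
    n_fractions = _require(doc, "n_fractions", path)
    if not isinstance(n_fractions, int):
        raise SchemaError(f"{path}.n_fractions: expected an integer")
    stages = tuple(doc.get("stages", DEFAULT_STAGES))
    steps = []
    for i, sd in enumerate(doc.get("steps", [])):
        spath = f"{path}.steps[{i}]"
        stage = _require(sd, "stage", spath)
        if stage not in stages:
            raise SchemaError(f"{spath}.stage: unknown stage {stage!r}")
        usages = []
        for j, ud in enumerate(sd.get("usages", [])):
            upath = f"{spath}.usages[{j}]"
            usages.append(
                ResourceUsage(
                    resource_id=_require(ud, "resource", upath),
                    minutes=_num_in(_require(ud, "minutes", upath), f"{upath}.minutes"),
                    headcount=int(ud.get("headcount", 1)),
                )
            )
        steps.append(
            ProcessStep(
                id=_require(sd, "id", spath),
                label=sd.get("label", sd["id"]),
                stage=stage,
                usages=tuple(usages),
                occurrence_prob=_num_in(
                    sd.get("occurrence_prob", 1), f"{spath}.occurrence_prob"
                ),
                per_fraction=bool(sd.get("per_fraction", False)),
            )
        )
    return Workflow(
        modality=modality, n_fractions=n_fractions, stages=stages, steps=tuple(steps)
    )


def read_workflow(path: str | Path) -> Workflow:
    """Read a workflow from a YAML (or JSON) process-map file."""
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise SchemaError(f"{path}: unparseable YAML/JSON: {exc}") from exc
    return workflow_from_dict(doc, path=str(path))


def write_workflow(workflow: Workflow, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(workflow_to_dict(workflow), fh, sort_keys=False)


_RESOURCE_COLUMNS = [
    "id",
    "name",
    "category",
    "annual_cost",
    "annual_days",
    "daily_hours",
    "ccr",
    "useful_life_years",
]


def read_resources(path: str | Path) -> ResourceTable:
    """Read a resource table from CSV (empty cell = absent optional field)."""
    df = pd.read_csv(path, dtype={"id": str, "name": str, "category": str})
    missing = [c for c in ("id", "name", "category") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: resource CSV missing columns {missing}")

    def opt(row, col):
        if col not in df.columns:
            return None
        v = row[col]
        return None if pd.isna(v) else float(v)

    return ResourceTable(
        Resource(
            id=row["id"],
            name=row["name"],
            category=row["category"],
            annual_cost=opt(row, "annual_cost"),
            annual_days=opt(row, "annual_days"),
            daily_hours=opt(row, "daily_hours"),
            ccr=opt(row, "ccr"),
            useful_life_years=opt(row, "useful_life_years"),
        )
        for _, row in df.iterrows()
    )


def write_resources(table: ResourceTable, path: str | Path) -> None:
    rows = [{c: getattr(r, c) for c in _RESOURCE_COLUMNS} for r in table.values()]
    pd.DataFrame(rows, columns=_RESOURCE_COLUMNS).to_csv(path, index=False)
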