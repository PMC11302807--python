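"""What-if interventions on a process map and the savings they yield.

An intervention is a named list of edits to a workflow: removing a step,
subtracting minutes from the steps that engage a set of resources
(optionally per treatment fraction), or scaling a step's durations.  A
dose-rate edit is a convenience form of a minutes reduction: raising the
accelerator dose rate from ``old`` to ``new`` MU/min shrinks the
MU-delivery portion of beam-on time by the factor (1 - old/new).

Savings are measured honestly: the edited workflow is re-costed with the
same TDABC engine and subtracted from the baseline, decomposed into
personnel, equipment, and space components.  Time saved is tracked as
elapsed workflow minutes removed per course (a 25-minute task shortened
by 25 minutes saves 25 minutes of wall clock, however many staff were in
the room).

Interventions may declare prerequisites (``requires``) — e.g. an
incremental delivery-time gain that only exists on top of another
technology — and ``combine`` applies a suite in dependency order,
reporting per-intervention and cumulative savings.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence, Union

import yaml

from .model import ProcessStep, ResourceTable, ResourceUsage, SchemaError, Workflow
from .tdabc import CostBreakdown, compare, rollup

__all__ = [
    "ClampWarning",
    "AffectedResource",
    "RemoveStep",
    "ReduceMinutes",
    "ScaleMinutes",
    "DoseRateReduction",
    "Intervention",
    "SavingsBreakdown",
    "ApplyReport",
    "dose_rate_delta",
    "apply",
    "apply_detailed",
    "savings",
    "combine",
    "CombinedResult",
    "read_interventions",
]


class ClampWarning(UserWarning):
    """An edit asked to remove more minutes than the workflow contains."""


@dataclass(frozen=True)
class AffectedResource:
    """A member of an edit's resource set: who/what the edit touches and,
    for personnel, how many heads are engaged simultaneously."""

    resource_id: str
    headcount: int = 1


@dataclass(frozen=True)
class RemoveStep:
    step_id: str


@dataclass(frozen=True)
class ReduceMinutes:
    """Remove ``delta_minutes`` per occurrence (per head) from the steps
    engaging each affected resource, optionally limited to one stage and
    repeated every fraction."""

    resources: tuple[AffectedResource, ...]
    delta_minutes: float
    per_fraction: bool = False
    stage: str | None = None


@dataclass(frozen=True)
class ScaleMinutes:
    """Multiply a step's usage minutes by ``factor`` in [0, 1]."""

    step_id: str
    factor: float

    def __post_init__(self) -> None:
        if not 0 <= self.factor <= 1:
            raise ValueError(f"scale factor {self.factor} outside [0, 1]")


@dataclass(frozen=True)
class DoseRateReduction:
    """Beam-on time reduction from a dose-rate upgrade, expressed as the
    beam-limited minutes affected and the old/new rates in MU/min."""

    resources: tuple[AffectedResource, ...]
    beam_on_minutes: float
    old_rate: float
    new_rate: float
    per_fraction: bool = False
    stage: str | None = None

    def as_reduction(self) -> ReduceMinutes:
        return ReduceMinutes(
            resources=self.resources,
            delta_minutes=dose_rate_delta(
                self.beam_on_minutes, self.old_rate, self.new_rate
            ),
            per_fraction=self.per_fraction,
            stage=self.stage,
        )


Edit = Union[RemoveStep, ReduceMinutes, ScaleMinutes, DoseRateReduction]


@dataclass(frozen=True)
class Intervention:
    name: str
    edits: tuple[Edit, ...]
    requires: tuple[str, ...] = ()
    description: str = ""
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SavingsBreakdown:
    """Cost saving of an intervention, by resource category, plus the
    elapsed treatment-course minutes it removes."""

    personnel: float
    equipment: float
    space: float
    time_saved: float

    @property
    def total(self) -> float:
        return self.personnel + self.equipment + self.space


@dataclass
class ApplyReport:
    elapsed_minutes_removed: float = 0.0
    warnings: list[str] = field(default_factory=list)


def dose_rate_delta(beam_on_minutes: float, old_rate: float, new_rate: float) -> float:
    """Minutes saved when the MU-delivery time shrinks inversely with the
    dose rate: ``beam_on_minutes x (1 - old_rate/new_rate)``."""
    if old_rate <= 0 or new_rate <= 0:
        raise ValueError("dose rates must be positive")
    return beam_on_minutes * (1.0 - old_rate / new_rate)


def _step_duration(step: ProcessStep) -> float:
    return max((float(u.minutes) for u in step.usages), default=0.0)


def _apply_reduce(
    workflow: Workflow, edit: ReduceMinutes, report: ApplyReport
) -> Workflow:
    steps = list(workflow.steps)
    mult = workflow.n_fractions if edit.per_fraction else 1
    max_elapsed = 0.0
    for ar in edit.resources:
        needed = edit.delta_minutes * ar.headcount * mult  # person-minutes
        removed = 0.0
        for i, step in enumerate(steps):
            if needed <= removed:
                break
            if edit.stage is not None and step.stage != edit.stage:
                continue
            smult = float(step.occurrence_prob) * (
                workflow.n_fractions if step.per_fraction else 1
            )
            if smult <= 0:
                continue
            new_usages = []
            for u in step.usages:
                if u.resource_id != ar.resource_id or needed <= removed:
                    new_usages.append(u)
                    continue
                avail = float(u.minutes) * u.headcount * smult
                take = min(avail, needed - removed)
                removed += take
                new_minutes = u.minutes - _exactish(take / (u.headcount * smult), u.minutes)
                new_usages.append(replace(u, minutes=new_minutes))
            steps[i] = replace(step, usages=tuple(new_usages))
        if removed < needed - 1e-9:
            report.warnings.append(
                f"reduce_minutes: only {removed:.4g} of {needed:.4g} person-minutes "
                f"available for resource {ar.resource_id!r}; clamped at 0"
            )
        max_elapsed = max(max_elapsed, removed / (ar.headcount * 1.0))
    report.elapsed_minutes_removed += max_elapsed
    return workflow.with_steps(steps)


def _exactish(value: float, like) -> Union[float, Fraction]:
    """Keep Fraction arithmetic exact when the reduction itself is exact."""
    if isinstance(like, Fraction):
        frac = Fraction(value).limit_denominator(10**6)
        if abs(float(frac) - value) < 1e-12:
            return frac
    return value


def apply_detailed(
    workflow: Workflow,
    intervention: Intervention,
    applied: Iterable[str] = (),
) -> tuple[Workflow, ApplyReport]:
    """Apply an intervention, returning the edited workflow and a report of
    elapsed minutes removed and any clamping."""
    unmet = [r for r in intervention.requires if r not in set(applied)]
    if unmet:
        raise ValueError(
            f"intervention {intervention.name!r} requires {unmet} to be applied first"
        )
    report = ApplyReport()
    wf = workflow
    for edit in intervention.edits:
        if isinstance(edit, DoseRateReduction):
            edit = edit.as_reduction()
        if isinstance(edit, RemoveStep):
            step = wf.step(edit.step_id)  # KeyError on dangling id
            mult = float(step.occurrence_prob) * (
                wf.n_fractions if step.per_fraction else 1
            )
            report.elapsed_minutes_removed += _step_duration(step) * mult
            wf = wf.with_steps(s for s in wf.steps if s.id != edit.step_id)
        elif isinstance(edit, ReduceMinutes):
            wf = _apply_reduce(wf, edit, report)
        elif isinstance(edit, ScaleMinutes):
            step = wf.step(edit.step_id)
            mult = float(step.occurrence_prob) * (
                wf.n_fractions if step.per_fraction else 1
            )
            report.elapsed_minutes_removed += (
                (1.0 - edit.factor) * _step_duration(step) * mult
            )
            new_step = replace(
                step,
                usages=tuple(
                    replace(u, minutes=u.minutes * _factor_like(edit.factor, u.minutes))
                    for u in step.usages
                ),
            )
            wf = wf.with_steps(new_step if s.id == step.id else s for s in wf.steps)
        else:
            raise TypeError(f"unknown edit type {type(edit).__name__}")
    for msg in report.warnings:
        _warnings.warn(msg, ClampWarning, stacklevel=2)
    return wf, report


def _factor_like(factor: float, like):
    if isinstance(like, Fraction):
        frac = Fraction(factor).limit_denominator(10**6)
        if abs(float(frac) - factor) < 1e-12:
            return frac
    return factor


def apply(
    workflow: Workflow, intervention: Intervention, applied: Iterable[str] = ()
) -> Workflow:
    """Edited copy of ``workflow``; the baseline is never modified."""
    wf, _ = apply_detailed(workflow, intervention, applied)
    return wf


def _breakdown_savings(
    base: CostBreakdown, edited: CostBreakdown, time_saved: float
) -> SavingsBreakdown:
    diff = compare(base, edited)
    cats = diff.category_totals
    return SavingsBreakdown(
        personnel=cats["personnel"],
        equipment=cats["equipment"],
        space=cats["space"],
        time_saved=time_saved,
    )


def savings(
    workflow: Workflow,
    resource_table: ResourceTable,
    intervention: Intervention,
    applied: Iterable[str] = (),
) -> SavingsBreakdown:
    """Cost and time saved by one intervention against the baseline."""
    edited, report = apply_detailed(workflow, intervention, applied)
    return _breakdown_savings(
        rollup(workflow, resource_table),
        rollup(edited, resource_table),
        report.elapsed_minutes_removed,
    )


@dataclass
class CombinedResult:
    baseline_total: float
    reduced_total: float
    per_intervention: dict[str, SavingsBreakdown]
    combined: SavingsBreakdown
    final_workflow: Workflow


def _dependency_order(interventions: Sequence[Intervention]) -> list[Intervention]:
    pending = list(interventions)
    names = {iv.name for iv in pending}
    for iv in pending:
        for req in iv.requires:
            if req not in names:
                raise ValueError(
                    f"intervention {iv.name!r} requires {req!r}, not in the suite"
                )
    ordered: list[Intervention] = []
    done: set[str] = set()
    while pending:
        ready = [iv for iv in pending if set(iv.requires) <= done]
        if not ready:
            raise ValueError(
                "circular requirements among "
                + ", ".join(iv.name for iv in pending)
            )
        for iv in ready:
            ordered.append(iv)
            done.add(iv.name)
            pending.remove(iv)
    return ordered


def combine(
    workflow: Workflow,
    resource_table: ResourceTable,
    interventions: Sequence[Intervention],
) -> CombinedResult:
    """Apply a suite of interventions sequentially in dependency order.

    Per-intervention savings are incremental (measured against the state
    the suite has reached); when edits touch disjoint minutes these equal
    the stand-alone savings and the combined total is their sum.
    """
    baseline = rollup(workflow, resource_table)
    wf = workflow
    current = baseline
    per: dict[str, SavingsBreakdown] = {}
    total_time = 0.0
    for iv in _dependency_order(interventions):
        wf, report = apply_detailed(wf, iv, applied=per.keys())
        after = rollup(wf, resource_table)
        per[iv.name] = _breakdown_savings(
            current, after, report.elapsed_minutes_removed
        )
        total_time += report.elapsed_minutes_removed
        current = after
    combined = _breakdown_savings(baseline, current, total_time)
    return CombinedResult(
        baseline_total=baseline.grand_total,
        reduced_total=current.grand_total,
        per_intervention=per,
        combined=combined,
        final_workflow=wf,
    )


# ---------------------------------------------------------------------------
# YAML/JSON intervention files

def _edit_from_dict(doc: dict, path: str) -> Edit:
    kind = doc.get("kind")
    def resources():
        rs = doc.get("resources")
        if not rs:
            raise SchemaError(f"{path}: edit needs a non-empty 'resources' list")
        return tuple(
            AffectedResource(r["resource"], int(r.get("headcount", 1))) for r in rs
        )
    if kind == "remove_step":
        return RemoveStep(step_id=doc["step_id"])
    if kind == "reduce_minutes":
        return ReduceMinutes(
            resources=resources(),
            delta_minutes=float(doc["delta_minutes"]),
            per_fraction=bool(doc.get("per_fraction", False)),
            stage=doc.get("stage"),
        )
    if kind == "scale_minutes":
        return ScaleMinutes(step_id=doc["step_id"], factor=float(doc["factor"]))
    if kind == "dose_rate":
        return DoseRateReduction(
            resources=resources(),
            beam_on_minutes=float(doc["beam_on_minutes"]),
            old_rate=float(doc["old_rate"]),
            new_rate=float(doc["new_rate"]),
            per_fraction=bool(doc.get("per_fraction", False)),
            stage=doc.get("stage"),
        )
    raise SchemaError(f"{path}: unknown edit kind {kind!r}")


def interventions_from_dict(doc, path: str = "interventions") -> list[Intervention]:
    if not isinstance(doc, list):
        raise SchemaError(f"{path}: expected a list of interventions")
    out = []
    for i, ivd in enumerate(doc):
        ipath = f"{path}[{i}]"
        if "name" not in ivd:
            raise SchemaError(f"{ipath}: missing required key 'name'")
        out.append(
            Intervention(
                name=ivd["name"],
                edits=tuple(
                    _edit_from_dict(ed, f"{ipath}.edits[{j}]")
                    for j, ed in enumerate(ivd.get("edits", []))
                ),
                requires=tuple(ivd.get("requires", [])),
                description=ivd.get("description", ""),
                metadata=ivd.get("metadata", {}),
            )
        )
    return out


def read_interventions(path: str | Path) -> list[Intervention]:
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise SchemaError(f"{path}: unparseable YAML/JSON: {exc}") from exc
    return interventions_from_dict(doc, path=str(path))
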