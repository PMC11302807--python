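"""Time-driven activity-based costing over process maps.

The engine follows the standard TDABC recipe: each resource's capacity
cost rate (CCR, USD/min) is its annual cost divided by its annual
available minutes; each step's cost is CCR x minutes x headcount,
weighted by the step's occurrence probability and repeated over treatment
fractions where applicable; step costs are summed into a grid indexed by
(resource, stage), from which stage, resource, and category totals and the
grand total all derive.

All arithmetic is carried in full precision; rounding to cents happens
only in the report emitters.  Difference grids (modality A minus
modality B) use the same container and may hold negative cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import (
    CATEGORIES,
    ProcessStep,
    Resource,
    ResourceTable,
    Workflow,
)

__all__ = [
    "CostBreakdown",
    "capacity_minutes",
    "compute_ccr",
    "effective_ccr",
    "step_cost",
    "rollup",
    "compare",
]


def capacity_minutes(resource: Resource) -> float:
    """Practical capacity of a resource in minutes per year."""
    if not resource.annual_days or resource.annual_days <= 0:
        raise ValueError(f"resource {resource.id!r}: annual_days must be positive")
    if not resource.daily_hours or resource.daily_hours <= 0:
        raise ValueError(f"resource {resource.id!r}: daily_hours must be positive")
    return resource.annual_days * resource.daily_hours * 60.0


def compute_ccr(resource: Resource) -> float:
    """Capacity cost rate in USD per minute, from annual cost and schedule."""
    if resource.annual_cost is None:
        raise ValueError(
            f"resource {resource.id!r}: annual_cost required to compute a CCR"
        )
    return resource.annual_cost / capacity_minutes(resource)


def effective_ccr(resource: Resource) -> float:
    """The CCR used in costing: a supplied rate wins over recomputation.

    Published rate tables often print the rounded CCR but not the salary
    behind it; the printed rate is then the reproducible quantity.
    """
    if resource.ccr is not None:
        return resource.ccr
    return compute_ccr(resource)


@dataclass
class CostBreakdown:
    """Cost cells indexed by (resource_id, stage), with marginal totals.

    ``cell_minutes`` accumulates resource-minutes (person-minutes for
    staffed usages) alongside the dollar cells so reports can show time
    and money on the same grid.
    """

    stages: tuple[str, ...]
    categories: dict[str, str] = field(default_factory=dict)
    cell_costs: dict[tuple[str, str], float] = field(default_factory=dict)
    cell_minutes: dict[tuple[str, str], float] = field(default_factory=dict)

    def add(
        self, resource_id: str, stage: str, cost: float, minutes: float, category: str
    ) -> None:
        key = (resource_id, stage)
        self.cell_costs[key] = self.cell_costs.get(key, 0.0) + cost
        self.cell_minutes[key] = self.cell_minutes.get(key, 0.0) + minutes
        self.categories.setdefault(resource_id, category)

    # -- marginals ---------------------------------------------------------

    @property
    def resource_totals(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for (rid, _), v in self.cell_costs.items():
            out[rid] = out.get(rid, 0.0) + v
        return out

    @property
    def stage_totals(self) -> dict[str, float]:
        out = {s: 0.0 for s in self.stages}
        for (_, stage), v in self.cell_costs.items():
            out[stage] = out.get(stage, 0.0) + v
        return out

    @property
    def category_totals(self) -> dict[str, float]:
        out = {c: 0.0 for c in CATEGORIES}
        for (rid, _), v in self.cell_costs.items():
            out[self.categories[rid]] += v
        return out

    @property
    def grand_total(self) -> float:
        return sum(self.cell_costs.values())

    @property
    def time_totals(self) -> dict[str, float]:
        """Resource-minutes per resource over the whole course."""
        out: dict[str, float] = {}
        for (rid, _), v in self.cell_minutes.items():
            out[rid] = out.get(rid, 0.0) + v
        return out

    def restrict(self, category: str) -> "CostBreakdown":
        """The sub-grid of a single resource category."""
        sub = CostBreakdown(stages=self.stages)
        for (rid, stage), v in self.cell_costs.items():
            if self.categories[rid] == category:
                sub.add(rid, stage, v, self.cell_minutes.get((rid, stage), 0.0), category)
        return sub

    def __add__(self, other: "CostBreakdown") -> "CostBreakdown":
        merged = CostBreakdown(stages=self.stages or other.stages)
        for bd in (self, other):
            for (rid, stage), v in bd.cell_costs.items():
                merged.add(
                    rid,
                    stage,
                    v,
                    bd.cell_minutes.get((rid, stage), 0.0),
                    bd.categories[rid],
                )
        return merged


def step_cost(
    step: ProcessStep, resource_table: ResourceTable, n_fractions: int
) -> CostBreakdown:
    """One step's contribution to the cost grid.

    Per usage: CCR x minutes x headcount x occurrence_prob, multiplied by
    the number of fractions if the step repeats each treatment session.
    """
    bd = CostBreakdown(stages=(step.stage,))
    mult = float(step.occurrence_prob) * (n_fractions if step.per_fraction else 1)
    for usage in step.usages:
        try:
            resource = resource_table[usage.resource_id]
        except KeyError:
            raise KeyError(
                f"step {step.id!r}: unknown resource {usage.resource_id!r}"
            ) from None
        minutes = float(usage.minutes) * usage.headcount * mult
        bd.add(
            usage.resource_id,
            step.stage,
            effective_ccr(resource) * minutes,
            minutes,
            resource.category,
        )
    return bd


def rollup(workflow: Workflow, resource_table: ResourceTable) -> CostBreakdown:
    """Total course cost: the sum of every step's contribution."""
    bd = CostBreakdown(stages=workflow.stages)
    for step in workflow.steps:
        contrib = step_cost(step, resource_table, workflow.n_fractions)
        for (rid, stage), v in contrib.cell_costs.items():
            bd.add(
                rid,
                stage,
                v,
                contrib.cell_minutes[(rid, stage)],
                contrib.categories[rid],
            )
    return bd


def compare(a: CostBreakdown, b: CostBreakdown) -> CostBreakdown:
    """Element-wise difference grid ``a - b`` (union of cells, missing = 0)."""
    stages = a.stages if len(a.stages) >= len(b.stages) else b.stages
    diff = CostBreakdown(stages=stages)
    keys = set(a.cell_costs) | set(b.cell_costs)
    for key in sorted(keys):
        rid, stage = key
        category = a.categories.get(rid) or b.categories.get(rid)
        diff.add(
            rid,
            stage,
            a.cell_costs.get(key, 0.0) - b.cell_costs.get(key, 0.0),
            a.cell_minutes.get(key, 0.0) - b.cell_minutes.get(key, 0.0),
            category,
        )
    return diff
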