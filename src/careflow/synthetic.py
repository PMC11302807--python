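"""Synthetic workflows and failure-mode registers with known ground truth.

The generators exist so every engine can be exercised, at scale and
property-tested, without any clinical data: multi-stage process maps
with log-normally distributed task durations, staffing headcounts,
occurrence probabilities, and per-fraction flags; and score registers
whose rater draws come from a discrete triangular distribution on the
1-10 TG-100 scale.

Workflow generation separates a *structure* seed (stages, steps, resource
assignment, headcounts, probabilities) from the *noise* seed (task
minutes).  Holding the structure fixed while varying the noise makes the
expected course cost analytic — E[lognormal(median m, sigma s)] =
m exp(s^2/2) — so Monte-Carlo recovery of the expected total is a real
test of the costing engine, not of the generator.

Register generation records its own ground truth (consensus scores,
RPNs, risk levels, top-fraction membership) with independent inline
arithmetic, for use as an oracle against the FMEA engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .fmea import FailureMode, Register, RiskMatrix, default_matrix
from .model import (
    ProcessStep,
    Resource,
    ResourceTable,
    ResourceUsage,
    Workflow,
)

__all__ = [
    "SynthWorkflowSpec",
    "WorkflowTruth",
    "synth_workflow",
    "SynthRegisterSpec",
    "RegisterTruth",
    "synth_register",
    "triangular_weights",
]


@dataclass(frozen=True)
class SynthWorkflowSpec:
    """Parameters of a synthetic multi-stage workflow.

    ``seed`` drives the stochastic task durations; ``structure_seed``
    drives everything else, so repeated draws with different ``seed``
    share one process-map skeleton.
    """

    seed: int = 0
    structure_seed: int = 1000
    n_stages: int = 4
    steps_per_stage: tuple[int, int] = (2, 5)  # inclusive range
    n_resources: int = 6
    ccr_range: tuple[float, float] = (0.3, 8.0)
    minutes_median: float = 15.0
    minutes_sigma: float = 0.5  # dispersion of log(minutes)
    headcount_probs: tuple[float, ...] = (0.8, 0.15, 0.05)  # P(1), P(2), P(3)
    p_certain: float = 0.8  # P(occurrence_prob == 1)
    prob_range: tuple[float, float] = (0.2, 0.9)
    p_per_fraction: float = 0.3
    n_fractions: int = 5


@dataclass
class WorkflowTruth:
    """Analytic moments of the rollup grand total, given the structure."""

    expected_total: float
    sd_total: float


def synth_workflow(
    spec: SynthWorkflowSpec,
) -> tuple[Workflow, ResourceTable, WorkflowTruth]:
    rng_struct = np.random.default_rng(spec.structure_seed)
    rng_noise = np.random.default_rng(spec.seed)

    categories = ["personnel", "equipment", "space"]
    resources = []
    for i in range(spec.n_resources):
        category = categories[i % 3] if spec.n_resources >= 3 else "personnel"
        resources.append(
            Resource(
                id=f"r{i:02d}",
                name=f"synthetic resource {i}",
                category=category,
                annual_days=260,
                daily_hours=8,
                ccr=round(float(rng_struct.uniform(*spec.ccr_range)), 2),
            )
        )
    table = ResourceTable(resources)

    e_min = spec.minutes_median * math.exp(spec.minutes_sigma**2 / 2)
    var_min = (
        spec.minutes_median**2
        * math.exp(spec.minutes_sigma**2)
        * (math.exp(spec.minutes_sigma**2) - 1)
    )

    stages = tuple(f"stage{i+1:02d}" for i in range(spec.n_stages))
    steps: list[ProcessStep] = []
    expected = 0.0
    variance = 0.0
    lo, hi = spec.steps_per_stage
    for stage in stages:
        n_steps = int(rng_struct.integers(lo, hi + 1)) if hi >= lo else 0
        for j in range(n_steps):
            resource = resources[int(rng_struct.integers(0, spec.n_resources))]
            if resource.category == "personnel":
                headcount = 1 + int(
                    rng_struct.choice(len(spec.headcount_probs), p=spec.headcount_probs)
                )
            else:
                headcount = 1
            if rng_struct.random() < spec.p_certain:
                prob = 1.0
            else:
                prob = float(rng_struct.uniform(*spec.prob_range))
            per_fraction = bool(rng_struct.random() < spec.p_per_fraction)
            minutes = float(
                rng_noise.lognormal(
                    mean=math.log(spec.minutes_median), sigma=spec.minutes_sigma
                )
            )
            steps.append(
                ProcessStep(
                    id=f"{stage}_s{j:02d}",
                    label=f"synthetic step {j} of {stage}",
                    stage=stage,
                    usages=(
                        ResourceUsage(
                            resource_id=resource.id,
                            minutes=minutes,
                            headcount=headcount,
                        ),
                    ),
                    occurrence_prob=prob,
                    per_fraction=per_fraction,
                )
            )
            mult = prob * (spec.n_fractions if per_fraction else 1)
            coeff = resource.ccr * headcount * mult
            expected += coeff * e_min
            variance += coeff**2 * var_min
    workflow = Workflow(
        modality=f"synthetic-{spec.structure_seed}",
        n_fractions=spec.n_fractions,
        stages=stages,
        steps=tuple(steps),
    )
    return workflow, table, WorkflowTruth(expected, math.sqrt(variance))


# ---------------------------------------------------------------------------
# registers

def triangular_weights(peak: int = 3) -> np.ndarray:
    """Discrete triangular weights on 1..10, peaked at ``peak`` and
    truncated at the scale ends."""
    w = np.array([11.0 - abs(v - peak) for v in range(1, 11)])
    return w / w.sum()


@dataclass(frozen=True)
class SynthRegisterSpec:
    seed: int = 0
    n_modes: int = 30
    n_raters: int = 3
    peak_O: int = 3
    peak_S: int = 3
    peak_D: int = 3
    roles: tuple[str, ...] = ("therapist", "physicist", "dosimetrist", "attending")


@dataclass
class RegisterTruth:
    """Generator-side bookkeeping, computed with independent arithmetic."""

    rpns: dict[str, Fraction] = field(default_factory=dict)
    levels: dict[str, str] = field(default_factory=dict)

    def top_ids(self, fraction: float = 0.2) -> set[str]:
        """Brute-force top-fraction RPN membership (ceiling k, ties kept)."""
        if not self.rpns:
            return set()
        ranked = sorted(self.rpns.items(), key=lambda kv: kv[1], reverse=True)
        k = math.ceil(fraction * len(ranked))
        threshold = ranked[k - 1][1]
        return {mid for mid, r in ranked if r >= threshold}


def synth_register(
    spec: SynthRegisterSpec, matrix: RiskMatrix | None = None
) -> tuple[Register, RegisterTruth]:
    if matrix is None:
        matrix = default_matrix()
    rng = np.random.default_rng(spec.seed)
    truth = RegisterTruth()
    modes = []
    scale = np.arange(1, 11)
    for i in range(spec.n_modes):
        mid = f"sfm{i:03d}"
        role = spec.roles[int(rng.integers(0, len(spec.roles)))]
        scores = {}
        for dim, peak in (("O", spec.peak_O), ("S", spec.peak_S), ("D", spec.peak_D)):
            raters = rng.choice(scale, size=spec.n_raters, p=triangular_weights(peak))
            scores[dim] = Fraction(int(raters.sum()), spec.n_raters)
        modes.append(
            FailureMode(
                id=mid,
                process_step_label=f"synthetic step {i}",
                role=role,
                description=f"synthetic failure mode {i}",
                O=scores["O"],
                S=scores["S"],
                D=scores["D"],
            )
        )
        # independent bookkeeping: product and grid lookup written out
        truth.rpns[mid] = scores["O"] * scores["S"] * scores["D"]
        s_idx = min(10, max(1, -(-scores["S"].numerator // scores["S"].denominator)))
        o_idx = min(10, max(1, -(-scores["O"].numerator // scores["O"].denominator)))
        truth.levels[mid] = "high" if s_idx >= 9 else matrix.grid[s_idx - 1][o_idx - 1]
    register = Register(
        modes=modes, metadata={"synthetic": True, "seed": spec.seed}
    )
    return register, truth
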