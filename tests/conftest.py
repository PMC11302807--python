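from fractions import Fraction

import pytest

from careflow import fixtures as fx
from careflow.model import ProcessStep, Resource, ResourceTable, ResourceUsage, Workflow


@pytest.fixture(scope="session")
def rate_card():
    return fx.study_resources()


@pytest.fixture(scope="session")
def mrgrt():
    return fx.study_workflow("MRgRT")


@pytest.fixture(scope="session")
def ctgrt():
    return fx.study_workflow("CTgRT")


@pytest.fixture()
def register():
    # function-scoped: tests mutate derived flags/levels
    return fx.study_register()


@pytest.fixture(scope="session")
def matrix():
    return fx.study_matrix()


@pytest.fixture(scope="session")
def interventions():
    return fx.study_interventions()


@pytest.fixture()
def toy_table():
    return ResourceTable(
        [
            Resource(id="rt", name="therapist", category="personnel",
                     annual_days=260, daily_hours=8, ccr=0.71),
            Resource(id="mach", name="machine", category="equipment",
                     annual_days=260, daily_hours=10, ccr=4.0),
            Resource(id="room", name="room", category="space",
                     annual_days=260, daily_hours=10, ccr=0.3),
        ]
    )


@pytest.fixture()
def toy_workflow():
    return Workflow(
        modality="toy",
        n_fractions=5,
        stages=("simulation", "treatment"),
        steps=(
            ProcessStep(
                id="sim", label="simulation scan", stage="simulation",
                usages=(
                    ResourceUsage("rt", minutes=Fraction(20), headcount=2),
                    ResourceUsage("mach", minutes=Fraction(20)),
                ),
            ),
            ProcessStep(
                id="tx", label="delivery", stage="treatment", per_fraction=True,
                usages=(
                    ResourceUsage("rt", minutes=30.0),
                    ResourceUsage("mach", minutes=30.0),
                    ResourceUsage("room", minutes=35.0),
                ),
            ),
            ProcessStep(
                id="opt", label="optional extra imaging", stage="treatment",
                occurrence_prob=0.5,
                usages=(ResourceUsage("mach", minutes=10.0),),
            ),
        ),
    )


def brute_force_total(workflow, table):
    """Independent per-usage enumeration of the course cost."""
    total = 0.0
    for step in workflow.steps:
        mult = float(step.occurrence_prob) * (
            workflow.n_fractions if step.per_fraction else 1
        )
        for u in step.usages:
            r = table[u.resource_id]
            ccr = (
                r.ccr
                if r.ccr is not None
                else r.annual_cost / (r.annual_days * r.daily_hours * 60.0)
            )
            total += ccr * float(u.minutes) * u.headcount * mult
    return total
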