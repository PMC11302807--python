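"""Scenario engine: edits, savings accounting, dose-rate arithmetic."""

import pytest

from careflow.scenario import (
    AffectedResource,
    ClampWarning,
    Intervention,
    ReduceMinutes,
    RemoveStep,
    ScaleMinutes,
    apply,
    apply_detailed,
    combine,
    dose_rate_delta,
    savings,
)
from careflow.tdabc import rollup


def _iv(name="iv", edits=(), requires=()):
    return Intervention(name=name, edits=tuple(edits), requires=tuple(requires))


class TestDoseRateDelta:
    def test_no_change_saves_nothing(self):
        assert dose_rate_delta(7, 600, 600) == 0.0

    def test_seven_minutes_at_600_to_1400(self):
        assert dose_rate_delta(7, 600, 1400) == pytest.approx(4.0)

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            dose_rate_delta(7, 0, 1400)
        with pytest.raises(ValueError):
            dose_rate_delta(7, 600, -1)


class TestApply:
    def test_remove_step(self, toy_workflow, toy_table):
        edited = apply(toy_workflow, _iv(edits=[RemoveStep("sim")]))
        assert [s.id for s in edited.steps] == ["tx", "opt"]
        # baseline untouched
        assert [s.id for s in toy_workflow.steps] == ["sim", "tx", "opt"]

    def test_remove_step_dangling_id_raises(self, toy_workflow):
        with pytest.raises(KeyError):
            apply(toy_workflow, _iv(edits=[RemoveStep("ghost")]))

    def test_null_reduction_is_cost_identical(self, toy_workflow, toy_table):
        edit = ReduceMinutes(
            resources=(AffectedResource("rt"),), delta_minutes=0.0
        )
        edited = apply(toy_workflow, _iv(edits=[edit]))
        assert rollup(edited, toy_table).grand_total == pytest.approx(
            rollup(toy_workflow, toy_table).grand_total
        )

    def test_overdraw_clamps_at_zero_with_warning(self, toy_workflow, toy_table):
        edit = ReduceMinutes(
            resources=(AffectedResource("room"),),
            delta_minutes=10_000,
            stage="treatment",
        )
        with pytest.warns(ClampWarning):
            edited = apply(toy_workflow, _iv(edits=[edit]))
        for step in edited.steps:
            for u in step.usages:
                assert u.minutes >= 0
        assert rollup(edited, toy_table).cell_costs.get(("room", "treatment"), 0.0) \
            == pytest.approx(0.0)

    def test_scale_minutes(self, toy_workflow, toy_table):
        edited = apply(toy_workflow, _iv(edits=[ScaleMinutes("tx", 0.5)]))
        base = rollup(toy_workflow, toy_table)
        after = rollup(edited, toy_table)
        assert after.cell_costs[("rt", "treatment")] == pytest.approx(
            base.cell_costs[("rt", "treatment")]
            - 0.5 * 30 * 5 * 0.71  # half of the per-fraction delivery minutes
        )

    def test_scale_factor_must_be_in_unit_interval(self):
        with pytest.raises(ValueError):
            ScaleMinutes("tx", 1.2)

    def test_unmet_requirement_raises(self, toy_workflow):
        iv = _iv(name="b", edits=[], requires=["a"])
        with pytest.raises(ValueError, match="requires"):
            apply(toy_workflow, iv)
        # satisfied when the prerequisite is in the applied context
        apply(toy_workflow, iv, applied={"a"})

    def test_per_fraction_reduction_scales_with_fractions(self, toy_workflow, toy_table):
        edit = ReduceMinutes(
            resources=(AffectedResource("rt"),), delta_minutes=2,
            per_fraction=True, stage="treatment",
        )
        sb = savings(toy_workflow, toy_table, _iv(edits=[edit]))
        assert sb.personnel == pytest.approx(2 * 5 * 0.71)
        assert sb.time_saved == pytest.approx(2 * 5)


class TestSavings:
    def test_consistency_with_rollup_difference(self, mrgrt, interventions):
        workflow, table = mrgrt
        for iv in interventions.values():
            if iv.requires:
                continue
            sb = savings(workflow, table, iv)
            edited = apply(workflow, iv)
            expected = (
                rollup(workflow, table).grand_total
                - rollup(edited, table).grand_total
            )
            assert sb.total == pytest.approx(expected, abs=1e-6)

    def test_category_decomposition_matches_rollups(self, mrgrt, interventions):
        workflow, table = mrgrt
        iv = interventions["auto_segmentation"]
        sb = savings(workflow, table, iv)
        base = rollup(workflow, table).category_totals
        after = rollup(apply(workflow, iv), table).category_totals
        assert sb.personnel == pytest.approx(base["personnel"] - after["personnel"])
        assert sb.equipment == pytest.approx(base["equipment"] - after["equipment"])
        assert sb.space == pytest.approx(base["space"] - after["space"])

    def test_shrinking_edits_never_increase_any_cell(self, mrgrt, interventions):
        workflow, table = mrgrt
        base = rollup(workflow, table)
        for iv in interventions.values():
            if iv.requires:
                continue
            after = rollup(apply(workflow, iv), table)
            for key, v in after.cell_costs.items():
                assert v <= base.cell_costs.get(key, 0.0) + 1e-9

    def test_null_intervention_saves_nothing(self, mrgrt):
        workflow, table = mrgrt
        sb = savings(workflow, table, _iv(edits=[]))
        assert sb.total == 0.0 and sb.time_saved == 0.0


class TestCombine:
    def test_empty_suite_keeps_baseline(self, mrgrt):
        workflow, table = mrgrt
        result = combine(workflow, table, [])
        assert result.reduced_total == pytest.approx(result.baseline_total)

    def test_disjoint_single_step_edits_commute(self, toy_workflow, toy_table):
        a = _iv(name="a", edits=[ScaleMinutes("sim", 0.5)])
        b = _iv(name="b", edits=[ScaleMinutes("tx", 0.5)])
        ab = combine(toy_workflow, toy_table, [a, b])
        ba = combine(toy_workflow, toy_table, [b, a])
        assert ab.reduced_total == pytest.approx(ba.reduced_total)
        assert ab.combined.total == pytest.approx(ba.combined.total)

    def test_disjoint_savings_sum_to_combined(self, mrgrt, interventions):
        workflow, table = mrgrt
        suite = [interventions["auto_segmentation"], interventions["synthetic_ct"]]
        result = combine(workflow, table, suite)
        individual = sum(
            savings(workflow, table, iv).total for iv in suite
        )
        assert result.combined.total == pytest.approx(individual, abs=1e-6)

    def test_requirement_ordering_resolved(self, mrgrt, interventions):
        workflow, table = mrgrt
        # vmat_delivery requires mlc_tracking; pass them in the wrong order
        suite = [interventions["vmat_delivery"], interventions["mlc_tracking"]]
        result = combine(workflow, table, suite)
        assert set(result.per_intervention) == {"mlc_tracking", "vmat_delivery"}

    def test_missing_dependency_rejected(self, mrgrt, interventions):
        workflow, table = mrgrt
        with pytest.raises(ValueError, match="requires"):
            combine(workflow, table, [interventions["vmat_delivery"]])

    def test_circular_dependency_rejected(self, toy_workflow, toy_table):
        a = _iv(name="a", requires=["b"])
        b = _iv(name="b", requires=["a"])
        with pytest.raises(ValueError, match="circular"):
            combine(toy_workflow, toy_table, [a, b])


def test_elapsed_time_of_removed_step_counts_duration_once(toy_workflow, toy_table):
    # removing the simulation step (20 min, 2 staff + machine) frees 20
    # elapsed minutes, not 40 person-minutes
    _, report = apply_detailed(toy_workflow, _iv(edits=[RemoveStep("sim")]))
    assert report.elapsed_minutes_removed == pytest.approx(20.0)
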