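"""Decision tree: categorization, worst-case and test-result assessments,
workflow orchestration, and the finite-space exhaustiveness guarantee."""

import itertools

import pytest

from prisafe import (
    AssessmentStage,
    Category,
    Disposition,
    DoseContext,
    EvidenceCode,
    MeasurementRecord,
    PriRecord,
    TestPoint as Point,
    ToxicityProfile,
    UsageStage,
    assign_test_point,
    categorize,
    run_workflow,
    step2a_worst_case,
    step2b_with_results,
)
from prisafe.core_types import SAFE_EVIDENCE, SEVERE_EVIDENCE


def _pri(conc=100.0, codes=frozenset({EvidenceCode.medium_toxicity}),
         stage=UsageStage.upstream, **kw):
    return PriRecord(
        id=kw.pop("id", "P1"), name="impurity", usage_stage=stage,
        usage_concentration=conc, evidence_codes=codes, **kw,
    )


def _valid_evidence_subsets():
    codes = list(EvidenceCode)
    for r in range(len(codes) + 1):
        for combo in itertools.combinations(codes, r):
            s = frozenset(combo)
            if (s & SAFE_EVIDENCE) and (s & SEVERE_EVIDENCE):
                continue
            if EvidenceCode.no_data in s and len(s) > 1:
                continue
            yield s


class TestCategorize:
    def test_gras_is_known_safe(self):
        assert categorize(_pri(codes=frozenset({EvidenceCode.GRAS})), None) is Category.A

    def test_medium_toxicity_with_noel_is_b2(self):
        tox = ToxicityProfile(noel=1.0)
        assert categorize(_pri(), tox) is Category.B2

    def test_medium_toxicity_without_dose_data_is_b1(self):
        assert categorize(_pri(), ToxicityProfile(ld50=100.0)) is Category.B1
        assert categorize(_pri(), None) is Category.B1

    def test_no_data_assessed_on_severe_branch(self):
        assert categorize(_pri(codes=frozenset({EvidenceCode.no_data})), None) is Category.C
        assert categorize(_pri(codes=frozenset()), None) is Category.C

    def test_genotoxic_is_category_c(self):
        assert categorize(
            _pri(codes=frozenset({EvidenceCode.genotoxic})), ToxicityProfile(noel=1.0)
        ) is Category.C

    def test_mixed_evidence_takes_severe_branch(self):
        codes = frozenset({EvidenceCode.metabolite, EvidenceCode.medium_toxicity})
        assert categorize(_pri(codes=codes), ToxicityProfile(noel=1.0)) is Category.B2


class TestExhaustiveness:
    @pytest.mark.parametrize("noel,ld50,pde", list(itertools.product(
        [None, 1.0], [None, 200.0], [None, 5000.0])))
    def test_every_combination_reaches_one_terminal(self, noel, ld50, pde):
        """Every syntactically valid (evidence, data-availability)
        combination flows to exactly one terminal disposition."""
        tox = ToxicityProfile(noel=noel, ld50=ld50, established_pde=pde)
        ctx = DoseContext(product_dose=500.0, product_protein_concentration=50.0,
                          isf_threshold=1000.0)
        for codes in _valid_evidence_subsets():
            pri = _pri(codes=codes)
            category = categorize(pri, tox)
            assert category in Category
            report = run_workflow([pri], {pri.id: tox}, ctx)
            assert len(report.outcomes) == 1
            outcome = report.outcomes[0]
            assert outcome.disposition in Disposition
            assert sum(report.disposition_counts.values()) == 1
            if category is Category.A:
                assert outcome.stage is AssessmentStage.step1


class TestStep2a:
    def test_b2_below_pde_passes(self, ctx):
        tox = ToxicityProfile(noel=1.0)  # PDE 5,000 μg/day at defaults
        outcome = step2a_worst_case(_pri(conc=100.0), tox, ctx)  # dose 1,000
        assert outcome.disposition is Disposition.no_safety_risk
        assert outcome.metrics["pde"] == pytest.approx(5000.0)

    def test_b2_above_pde_needs_testing(self, ctx):
        tox = ToxicityProfile(noel=1.0)
        outcome = step2a_worst_case(_pri(conc=2000.0), tox, ctx)  # dose 20,000
        assert outcome.disposition is Disposition.testing_required

    def test_severe_branch_below_ttc_passes(self, ctx):
        pri = _pri(conc=0.01, codes=frozenset({EvidenceCode.genotoxic}))
        outcome = step2a_worst_case(pri, None, ctx)  # dose 0.1 vs TTC 1.5
        assert outcome.disposition is Disposition.no_safety_risk
        assert outcome.metrics["pri_dose"] == pytest.approx(0.1)

    def test_b1_isf_path_strict_threshold(self):
        ctx = DoseContext(product_dose=500.0, product_protein_concentration=50.0,
                          isf_threshold=1000.0)
        tox = ToxicityProfile(ld50=20.0)  # 1e6 μg toxicity dose at 50 kg
        passing = step2a_worst_case(_pri(conc=50.0), tox, ctx)  # dose 500 → ISF 2000
        assert passing.disposition is Disposition.no_safety_risk
        failing = step2a_worst_case(_pri(conc=200.0), tox, ctx)  # ISF 500
        assert failing.disposition is Disposition.testing_required

    def test_b1_without_isf_inputs_escalates_to_ttc(self, ctx):
        """Missing LD50 or threshold escalates to the TTC comparison
        instead of passing on absent data."""
        outcome = step2a_worst_case(_pri(conc=100.0), None, ctx)  # dose 1,000
        assert outcome.disposition is Disposition.testing_required
        assert "TTC" in outcome.rationale

    def test_category_a_rejected(self, ctx):
        with pytest.raises(ValueError, match="Category A"):
            step2a_worst_case(_pri(codes=frozenset({EvidenceCode.GRAS})), None, ctx)


class TestStep2b:
    def test_lod_result_passes_with_bound_annotation(self, ctx):
        tox = ToxicityProfile(noel=1.0)
        outcome = step2b_with_results(_pri(conc=2000.0), tox, ctx,
                                      measured_or_lod=0.5,
                                      measurement_protein=5.0, is_lod=True)
        assert outcome.disposition is Disposition.no_safety_risk
        assert outcome.stage is AssessmentStage.step2b
        assert "upper bound" in outcome.rationale

    def test_measured_dose_above_pde_requires_action(self, ctx):
        tox = ToxicityProfile(noel=1.0)
        outcome = step2b_with_results(_pri(conc=2000.0), tox, ctx,
                                      measured_or_lod=100.0,
                                      measurement_protein=5.0)
        assert outcome.disposition is Disposition.action_required


class TestTestPointAssignment:
    @pytest.mark.parametrize("stage,expected", [
        (UsageStage.cell_banking, Point.proA_pool),
        (UsageStage.upstream, Point.proA_pool),
        (UsageStage.harvest, Point.proA_pool),
        (UsageStage.downstream_pre_proA, Point.proA_pool),
        (UsageStage.downstream_pre_CEX, Point.cex_pool),
        (UsageStage.downstream_post_CEX, Point.viral_filtration_pool),
        (UsageStage.formulation, Point.viral_filtration_pool),
    ])
    def test_leveraged_clearance_placement(self, stage, expected):
        assert assign_test_point(_pri(stage=stage)) is expected

    def test_platform_switch_uses_viral_filtration_everywhere(self):
        pri = _pri(stage=UsageStage.upstream)
        assert assign_test_point(pri, platform_single_point=True) is \
            Point.viral_filtration_pool


class TestRunWorkflow:
    def test_worked_example_counts(self, example_dataset):
        """The worked inventory: 96 eliminated at Step 1, 9 assessed as B2,
        3 in the testing plan, and all 105 clear after LOD-based Step 2b."""
        d = example_dataset
        report = run_workflow(d.inventory, d.tox_map, d.dose_context,
                              d.measurements)
        assert report.n_pris == 105
        assert report.category_counts["A"] == 96
        assert report.category_counts["B2"] == 9
        assert report.category_counts["C"] == 0
        assert len(report.testing_plan) == 3
        assert report.disposition_counts["no_safety_risk"] == 105

    def test_without_measurements_three_remain_flagged(self, example_dataset):
        d = example_dataset
        report = run_workflow(d.inventory, d.tox_map, d.dose_context)
        assert report.disposition_counts["testing_required"] == 3
        assert report.disposition_counts["no_safety_risk"] == 102

    def test_empty_inventory(self, ctx):
        report = run_workflow([], {}, ctx)
        assert report.n_pris == 0
        assert sum(report.category_counts.values()) == 0
        assert report.testing_plan == ()

    def test_single_genotoxic_without_measurement(self, ctx):
        pri = _pri(conc=100.0, codes=frozenset({EvidenceCode.genotoxic}))
        report = run_workflow([pri], {}, ctx)
        assert report.outcomes[0].category is Category.C
        assert report.outcomes[0].disposition is Disposition.testing_required
        assert len(report.testing_plan) == 1

    def test_counts_sum_to_inventory_size(self, example_dataset):
        d = example_dataset
        report = run_workflow(d.inventory, d.tox_map, d.dose_context,
                              d.measurements)
        assert sum(report.category_counts.values()) == report.n_pris
        assert sum(report.disposition_counts.values()) == report.n_pris

    def test_category_a_never_in_testing_plan(self, example_dataset):
        d = example_dataset
        report = run_workflow(d.inventory, d.tox_map, d.dose_context)
        a_ids = {o.pri_id for o in report.outcomes if o.category is Category.A}
        assert not a_ids & {e.pri_id for e in report.testing_plan}

    def test_unmatched_measurement_ids_reported(self, ctx):
        pri = _pri(conc=100.0)
        meas = {"ghost": MeasurementRecord(
            pri_id="ghost", test_point=Point.viral_filtration_pool,
            concentration=0.5, is_lod=True, protein_concentration=5.0)}
        report = run_workflow([pri], {"P1": ToxicityProfile(noel=1.0)}, ctx, meas)
        assert report.unmatched_measurement_ids == ("ghost",)

    def test_deterministic_given_identical_inputs(self, example_dataset):
        d = example_dataset
        r1 = run_workflow(d.inventory, d.tox_map, d.dose_context, d.measurements)
        r2 = run_workflow(d.inventory, d.tox_map, d.dose_context, d.measurements)
        assert r1.model_dump() == r2.model_dump()

    def test_outcomes_sorted_by_id(self, example_dataset):
        d = example_dataset
        report = run_workflow(d.inventory, d.tox_map, d.dose_context)
        ids = [o.pri_id for o in report.outcomes]
        assert ids == sorted(ids)


class TestMonotonicity:
    @pytest.mark.parametrize("conc", [1.0, 10.0, 100.0, 500.0, 2000.0])
    def test_lower_usage_never_flips_pass_to_fail(self, ctx, conc):
        """If a PRI passes worst-case at some usage concentration, it also
        passes at every lower concentration."""
        tox = ToxicityProfile(noel=1.0)
        outcome = step2a_worst_case(_pri(conc=conc), tox, ctx)
        if outcome.disposition is Disposition.no_safety_risk:
            for lower in (conc / 2, conc / 10, conc / 100):
                weaker = step2a_worst_case(_pri(conc=lower), tox, ctx)
                assert weaker.disposition is Disposition.no_safety_risk
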