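"""The two-step risk-assessment decision tree and workflow orchestration.

Step 1 categorises each impurity from its toxicological evidence; known-safe
(Category A) impurities leave the workflow immediately.  Step 2a assesses the
rest under the worst-case assumption that the impurity co-purifies with the
product unchanged — the PRI-to-protein mass ratio at the introduction point
is carried to drug substance with no clearance credit.  Impurities that fail
worst-case enter the testing plan; Step 2b repeats the comparison with the
measured (or assay-LOD) concentration at the test point, and a failure there
means the process or the assay must be improved.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

from pydantic import BaseModel, ConfigDict, Field

from .core_types import (
    AssessmentOutcome,
    AssessmentStage,
    Category,
    Disposition,
    DoseContext,
    MeasurementRecord,
    PriRecord,
    SAFE_EVIDENCE,
    SEVERE_EVIDENCE,
    TestingPlanEntry,
    TestPoint,
    ToxicityProfile,
    UsageStage,
    EvidenceCode,
)
from .risk_calculus import (
    PdeNotDerivableError,
    compute_isf,
    compute_pde,
    compute_pri_dose,
    isf_passes,
    margin_vs_limit,
    toxicity_dose_from_ld50,
)


# --------------------------------------------------------------------------
# Step 1 — categorization
# --------------------------------------------------------------------------

def categorize(pri: PriRecord, tox: Optional[ToxicityProfile]) -> Category:
    """Assign the risk category from evidence codes and data availability.

    * severe evidence (genotoxic/carcinogenic) → C
    * no evidence at all, or an explicit no-data code → C (most
      conservative assumption)
    * evidence entirely within the known-safe set → A
    * otherwise medium risk: B2 when a PDE is established or derivable
      (NOEL/LOEL available), else B1

    Mixed evidence (a safe code alongside medium toxicity) takes the more
    severe branch; contradictory combinations are rejected at record
    construction.
    """
    codes = pri.evidence_codes
    if codes & SEVERE_EVIDENCE:
        return Category.C
    if not codes or codes == {EvidenceCode.no_data}:
        return Category.C
    if codes <= SAFE_EVIDENCE:
        return Category.A
    # medium-toxicity branch (possibly mixed with safe codes)
    if tox is not None and (
        tox.established_pde is not None or tox.noel is not None or tox.loel is not None
    ):
        return Category.B2
    return Category.B1


def _pde_limit(tox: ToxicityProfile, ctx: DoseContext) -> float:
    """μg/day limit for a B2 PRI: the established PDE when available,
    otherwise derived from NOEL/LOEL."""
    if tox.established_pde is not None and tox.established_pde > 0:
        return tox.established_pde
    return compute_pde(tox, ctx)


# --------------------------------------------------------------------------
# Step 2 — risk assessment
# --------------------------------------------------------------------------

def _assess_dose(
    pri: PriRecord,
    tox: Optional[ToxicityProfile],
    ctx: DoseContext,
    category: Category,
    dose_ug: float,
    stage: AssessmentStage,
    dose_source: str,
    fail_disposition: Disposition,
    is_lod_bound: bool = False,
) -> AssessmentOutcome:
    """Shared dose-vs-limit core of Steps 2a and 2b.

    The per-product-dose amount (μg) is compared as a daily dose (μg/day),
    i.e. one product dose per day is assumed — conservative for less
    frequent dosing regimens.
    """
    metrics: dict[str, float] = {"pri_dose": dose_ug}
    effective_category = category

    if category is Category.B2:
        limit = _pde_limit(tox, ctx)  # type: ignore[arg-type]
        metrics["pde"] = limit
        result = margin_vs_limit(dose_ug, limit)
        metrics["margin"] = result.margin
        basis = f"dose vs PDE {limit:.6g} μg/day"
        passed = result.passed
    elif category is Category.B1:
        if tox is not None and tox.ld50 is not None and ctx.isf_threshold is not None:
            toxicity_dose = toxicity_dose_from_ld50(tox.ld50, ctx.body_weight)
            isf = compute_isf(toxicity_dose, dose_ug)
            metrics["isf"] = isf
            passed = isf_passes(isf, ctx.isf_threshold)
            basis = (
                f"ISF {isf:.6g} vs threshold {ctx.isf_threshold:.6g} "
                f"(LD50 × {ctx.body_weight:g} kg)"
            )
        else:
            # no LD50 or no configured threshold: escalate to the TTC branch
            # rather than pass on missing data
            effective_category = Category.B1
            result = margin_vs_limit(dose_ug, ctx.ttc)
            metrics["margin"] = result.margin
            metrics["ttc"] = ctx.ttc
            passed = result.passed
            basis = (
                "ISF path unavailable (missing LD50 or ISF threshold); "
                f"escalated to TTC {ctx.ttc:g} μg/day"
            )
    else:  # Category C (including no-data)
        result = margin_vs_limit(dose_ug, ctx.ttc)
        metrics["margin"] = result.margin
        metrics["ttc"] = ctx.ttc
        passed = result.passed
        basis = f"dose vs TTC {ctx.ttc:g} μg/day"

    disposition = Disposition.no_safety_risk if passed else fail_disposition
    rationale = f"{dose_source}; {basis}; {'pass' if passed else 'fail'}"
    if is_lod_bound:
        rationale += "; dose is an upper bound (assay LOD substituted)"
    return AssessmentOutcome(
        pri_id=pri.id,
        category=effective_category,
        stage=stage,
        disposition=disposition,
        metrics=metrics,
        rationale=rationale,
    )


def step2a_worst_case(
    pri: PriRecord, tox: Optional[ToxicityProfile], ctx: DoseContext
) -> AssessmentOutcome:
    """Worst-case assessment: full co-purification, no clearance credit.

    The PRI dose uses the usage concentration and the protein concentration
    at the introduction point, so the mass ratio carried into drug substance
    is the one at spiking time.
    """
    category = categorize(pri, tox)
    if category is Category.A:
        raise ValueError(f"{pri.id} is Category A; it does not enter Step 2")
    protein = ctx.protein_concentration_at(pri.usage_stage)
    dose = compute_pri_dose(pri.usage_concentration, protein, ctx.product_dose)
    return _assess_dose(
        pri,
        tox,
        ctx,
        category,
        dose,
        AssessmentStage.step2a,
        dose_source=(
            f"worst-case copurification from {pri.usage_stage.value} "
            f"({pri.usage_concentration:g} μg/ml at {protein:g} mg/ml protein)"
        ),
        fail_disposition=Disposition.testing_required,
    )


def step2b_with_results(
    pri: PriRecord,
    tox: Optional[ToxicityProfile],
    ctx: DoseContext,
    measured_or_lod: float,
    measurement_protein: float,
    is_lod: bool = False,
) -> AssessmentOutcome:
    """Re-assessment from an in-process test result (or its assay LOD for a
    non-detect).  A failure here is ``action_required``: either the process
    or the analytical method must be improved."""
    category = categorize(pri, tox)
    dose = compute_pri_dose(measured_or_lod, measurement_protein, ctx.product_dose)
    return _assess_dose(
        pri,
        tox,
        ctx,
        category,
        dose,
        AssessmentStage.step2b,
        dose_source=(
            f"in-process result {measured_or_lod:g} μg/ml at "
            f"{measurement_protein:g} mg/ml protein"
        ),
        fail_disposition=Disposition.action_required,
        is_lod_bound=is_lod,
    )


# --------------------------------------------------------------------------
# Test-point assignment
# --------------------------------------------------------------------------

_STAGE_TO_TEST_POINT: dict[UsageStage, TestPoint] = {
    UsageStage.cell_banking: TestPoint.proA_pool,
    UsageStage.upstream: TestPoint.proA_pool,
    UsageStage.harvest: TestPoint.proA_pool,
    UsageStage.downstream_pre_proA: TestPoint.proA_pool,
    UsageStage.downstream_pre_CEX: TestPoint.cex_pool,
    UsageStage.downstream_post_CEX: TestPoint.viral_filtration_pool,
    UsageStage.formulation: TestPoint.viral_filtration_pool,
}


def assign_test_point(
    pri: PriRecord, platform_single_point: bool = False
) -> TestPoint:
    """Choose the in-process test point for a flagged PRI.

    By default the earliest pool that still captures the step with the most
    clearance leverage for the introduction stage; the platform alternative
    places every test at the viral-filtration pool.
    """
    if platform_single_point:
        return TestPoint.viral_filtration_pool
    return _STAGE_TO_TEST_POINT[pri.usage_stage]


# --------------------------------------------------------------------------
# Workflow orchestration
# --------------------------------------------------------------------------

class WorkflowReport(BaseModel):
    """Full decision-tree run: one terminal outcome per PRI, the testing
    plan, summary tallies, and the configuration snapshot."""

    model_config = ConfigDict(frozen=True)

    outcomes: tuple[AssessmentOutcome, ...]
    testing_plan: tuple[TestingPlanEntry, ...]
    category_counts: Mapping[str, int] = Field(default_factory=dict)
    disposition_counts: Mapping[str, int] = Field(default_factory=dict)
    unmatched_measurement_ids: tuple[str, ...] = ()
    config_snapshot: Mapping[str, object] = Field(default_factory=dict)

    @property
    def n_pris(self) -> int:
        return len(self.outcomes)


def run_workflow(
    inventory: Iterable[PriRecord],
    tox_map: Mapping[str, ToxicityProfile],
    ctx: DoseContext,
    measurements: Optional[Mapping[str, MeasurementRecord]] = None,
    platform_single_test_point: bool = False,
) -> WorkflowReport:
    """Run the full management workflow over an inventory.

    Step 1 categorises everything and eliminates Category A; Step 2a runs
    worst-case assessments on the rest; Step 2b re-assesses any PRI with a
    supplied measurement.  Output ordering is deterministic (sorted by PRI
    id); measurement ids with no matching flagged PRI are reported, not
    dropped.
    """
    measurements = dict(measurements or {})
    records = sorted(inventory, key=lambda r: r.id)
    outcomes: list[AssessmentOutcome] = []
    plan: list[TestingPlanEntry] = []

    for pri in records:
        tox = tox_map.get(pri.id)
        category = categorize(pri, tox)
        if category is Category.A:
            outcomes.append(
                AssessmentOutcome(
                    pri_id=pri.id,
                    category=Category.A,
                    stage=AssessmentStage.step1,
                    disposition=Disposition.no_safety_risk,
                    rationale="known-to-be-safe evidence; eliminated at Step 1",
                )
            )
            continue

        outcome = step2a_worst_case(pri, tox, ctx)
        if outcome.disposition is Disposition.testing_required:
            meas = measurements.pop(pri.id, None)
            if meas is not None:
                point = meas.test_point
                lod = meas.concentration if meas.is_lod else None
                outcome = step2b_with_results(
                    pri,
                    tox,
                    ctx,
                    meas.concentration,
                    meas.protein_concentration,
                    is_lod=meas.is_lod,
                )
            else:
                point = assign_test_point(pri, platform_single_test_point)
                lod = None
            plan.append(
                TestingPlanEntry(pri_id=pri.id, test_point=point, assay_lod=lod)
            )
        outcomes.append(outcome)

    category_counts = {c.value: 0 for c in Category}
    disposition_counts = {d.value: 0 for d in Disposition}
    for o in outcomes:
        category_counts[o.category.value] += 1
        disposition_counts[o.disposition.value] += 1

    snapshot = {
        "product_dose_mg": ctx.product_dose,
        "product_protein_concentration_mg_ml": ctx.product_protein_concentration,
        "body_weight_kg": ctx.body_weight,
        "ttc_ug_day": ctx.ttc,
        "isf_threshold": ctx.isf_threshold,
        "modifying_factors": ctx.modifying_factors.model_dump(),
        "platform_single_test_point": platform_single_test_point,
    }
    return WorkflowReport(
        outcomes=tuple(outcomes),
        testing_plan=tuple(plan),
        category_counts=category_counts,
        disposition_counts=disposition_counts,
        unmatched_measurement_ids=tuple(sorted(measurements)),
        config_snapshot=snapshot,
    )
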