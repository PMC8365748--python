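"""Units-aware domain types shared across the package.

Unit conventions are fixed per field and enforced by construction:

* PRI concentrations        μg/ml
* protein concentrations    mg/ml
* product dose              mg
* NOEL / LOEL               mg/kg/day
* LD50                      mg/kg
* PDE, TTC, PRI daily dose  μg/day
* body weight               kg

Converters live at the I/O boundary only; everything downstream of these
models can do arithmetic without unit bookkeeping.  This matters because the
source quantities mix μg/ml, mg/ml and mg/kg, and a silent mix-up is a
1000-fold error in a safety margin.
"""

from __future__ import annotations

import enum
from typing import Mapping, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator


# --------------------------------------------------------------------------
# Enumerations
# --------------------------------------------------------------------------

class ChargeClass(str, enum.Enum):
    positive = "positive"
    negative = "negative"
    neutral = "neutral"
    zwitterionic = "zwitterionic"
    unknown = "unknown"


class HydrophobicityClass(str, enum.Enum):
    hydrophilic = "hydrophilic"
    moderate = "moderate"
    hydrophobic = "hydrophobic"
    unknown = "unknown"


class UsageStage(str, enum.Enum):
    """Where in the process a PRI is introduced."""

    cell_banking = "cell_banking"
    upstream = "upstream"
    harvest = "harvest"
    downstream_pre_proA = "downstream_pre_proA"
    downstream_pre_CEX = "downstream_pre_CEX"
    downstream_post_CEX = "downstream_post_CEX"
    formulation = "formulation"


class EvidenceCode(str, enum.Enum):
    """Toxicological evidence classes attached to a PRI.

    ``metabolite``, ``GRAS`` and ``approved_excipient`` are the
    known-to-be-safe codes; ``genotoxic``/``carcinogenic`` mark severe
    toxicity; ``no_data`` means no evidence at all and is assessed on the
    most conservative branch.
    """

    metabolite = "metabolite"
    GRAS = "GRAS"
    approved_excipient = "approved_excipient"
    medium_toxicity = "medium_toxicity"
    genotoxic = "genotoxic"
    carcinogenic = "carcinogenic"
    no_data = "no_data"


SAFE_EVIDENCE = frozenset(
    {EvidenceCode.metabolite, EvidenceCode.GRAS, EvidenceCode.approved_excipient}
)
SEVERE_EVIDENCE = frozenset({EvidenceCode.genotoxic, EvidenceCode.carcinogenic})


class Ld50Route(str, enum.Enum):
    iv = "iv"
    sc = "sc"
    oral = "oral"
    other = "other"


class Category(str, enum.Enum):
    """Risk class: A known-safe, B1 medium without PDE, B2 medium with PDE,
    C severe toxicity (or no data at all)."""

    A = "A"
    B1 = "B1"
    B2 = "B2"
    C = "C"


class AssessmentStage(str, enum.Enum):
    step1 = "step1"
    step2a = "step2a"
    step2b = "step2b"


class Disposition(str, enum.Enum):
    no_safety_risk = "no_safety_risk"
    testing_required = "testing_required"
    action_required = "action_required"


class TestPoint(str, enum.Enum):
    proA_pool = "proA_pool"
    cex_pool = "cex_pool"
    viral_filtration_pool = "viral_filtration_pool"


# --------------------------------------------------------------------------
# Records
# --------------------------------------------------------------------------

class PriRecord(BaseModel):
    """One process-related impurity and the evidence attached to it."""

    model_config = ConfigDict(frozen=True)

    id: str = Field(min_length=1)
    name: str = Field(min_length=1)
    molecular_weight: Optional[float] = Field(default=None, gt=0)  # g/mol
    charge_class: ChargeClass = ChargeClass.unknown
    hydrophobicity_class: HydrophobicityClass = HydrophobicityClass.unknown
    surfactant: bool = False
    critical_micelle_concentration: Optional[float] = Field(default=None, gt=0)  # μg/ml
    usage_stage: UsageStage
    usage_concentration: float = Field(ge=0)  # μg/ml
    evidence_codes: frozenset[EvidenceCode] = frozenset()

    @model_validator(mode="after")
    def _check_evidence_consistency(self) -> "PriRecord":
        codes = self.evidence_codes
        severe = codes & SEVERE_EVIDENCE
        safe = codes & SAFE_EVIDENCE
        if severe and safe:
            raise ValueError(
                f"contradictory evidence for {self.id}: severe codes "
                f"{sorted(c.value for c in severe)} cannot coexist with "
                f"safe codes {sorted(c.value for c in safe)}"
            )
        if EvidenceCode.no_data in codes and len(codes) > 1:
            raise ValueError(
                f"contradictory evidence for {self.id}: no_data cannot be "
                "combined with other evidence codes"
            )
        return self


class ToxicityProfile(BaseModel):
    """Toxicology reference values for one PRI.

    NOEL/LOEL feed the PDE derivation; LD50 feeds the impurity-safety-factor
    path; ``established_pde`` short-circuits the derivation when a guideline
    value already exists.
    """

    model_config = ConfigDict(frozen=True)

    noel: Optional[float] = Field(default=None, ge=0)  # mg/kg/day
    loel: Optional[float] = Field(default=None, ge=0)  # mg/kg/day
    ld50: Optional[float] = Field(default=None, ge=0)  # mg/kg
    ld50_route: Ld50Route = Ld50Route.other
    established_pde: Optional[float] = Field(default=None, ge=0)  # μg/day
    severe_toxicity: bool = False


class ModifyingFactors(BaseModel):
    """PDE modifying factors, all dimensionless multipliers ≥ 1.

    F1 interspecies extrapolation, F2 inter-individual variability (fixed at
    10 by convention), F3 short study duration, F4 severe-toxicity penalty,
    F5 applied when the point of departure is a LOEL rather than a NOEL.
    The remaining factors default to 1 and must be set deliberately — the
    library refuses to invent toxicological judgment.
    """

    model_config = ConfigDict(frozen=True)

    f1: float = Field(default=1.0, ge=1)
    f2: float = Field(default=10.0, ge=1)
    f3: float = Field(default=1.0, ge=1)
    f4: float = Field(default=1.0, ge=1)
    f5: float = Field(default=1.0, ge=1)

    @property
    def product(self) -> float:
        return self.f1 * self.f2 * self.f3 * self.f4 * self.f5


class DoseContext(BaseModel):
    """Product dosing context shared by every dose computation.

    ``stage_protein_concentrations`` optionally overrides the protein
    concentration at a PRI's introduction point; absent an entry, the
    product protein concentration is used, which keeps the worst-case
    PRI-to-protein mass ratio conservative.
    """

    model_config = ConfigDict(frozen=True)

    product_dose: float = Field(gt=0)  # mg
    product_protein_concentration: float = Field(gt=0)  # mg/ml
    body_weight: float = Field(default=50.0, gt=0)  # kg; conventional adult
    modifying_factors: ModifyingFactors = ModifyingFactors()
    ttc: float = Field(default=1.5, gt=0)  # μg/day, lifelong exposure
    isf_threshold: Optional[float] = Field(default=None, gt=0)
    stage_protein_concentrations: Mapping[UsageStage, float] = Field(
        default_factory=dict
    )

    def protein_concentration_at(self, stage: UsageStage) -> float:
        """Protein concentration (mg/ml) at a PRI's introduction point."""
        value = dict(self.stage_protein_concentrations).get(stage)
        if value is not None:
            if value <= 0:
                raise ValueError(f"protein concentration at {stage} must be > 0")
            return value
        return self.product_protein_concentration


class ClearanceMeasurement(BaseModel):
    """Paired PRI/protein concentrations across one unit operation.

    Non-detect results must be substituted with the assay LOD *before*
    construction, flagged via ``final_is_lod``; zero concentrations are
    rejected so every clearance fold is finite.
    """

    model_config = ConfigDict(frozen=True)

    step_name: str = Field(min_length=1)
    initial_pri: float = Field(gt=0)  # μg/ml
    initial_protein: float = Field(gt=0)  # mg/ml
    final_pri: float = Field(gt=0)  # μg/ml
    final_protein: float = Field(gt=0)  # mg/ml
    final_is_lod: bool = False


class ProfilePoint(BaseModel):
    model_config = ConfigDict(frozen=True)

    diavolume: float = Field(ge=0)
    concentration: float = Field(gt=0)  # μg/ml
    is_lod: bool = False


class DiafiltrationProfile(BaseModel):
    """Concentration-vs-diavolume series from a constant-volume
    diafiltration, anchored at N=0."""

    model_config = ConfigDict(frozen=True)

    c0: float = Field(gt=0)  # μg/ml
    points: tuple[ProfilePoint, ...]

    @model_validator(mode="after")
    def _check_points(self) -> "DiafiltrationProfile":
        if not self.points:
            raise ValueError("profile must contain at least one point")
        dvs = [p.diavolume for p in self.points]
        if any(b <= a for a, b in zip(dvs, dvs[1:])):
            raise ValueError("diavolumes must be strictly increasing")
        first = self.points[0]
        if first.diavolume != 0:
            raise ValueError("profile must start at diavolume 0")
        if abs(first.concentration - self.c0) > 1e-6 * max(self.c0, 1.0):
            raise ValueError("first point concentration must equal c0")
        return self


class SievingFit(BaseModel):
    """Result of fitting the exponential washout model to a profile."""

    model_config = ConfigDict(frozen=True)

    s: float  # sieving coefficient, dimensionless
    s_loglinear: float  # closed-form log-linear estimate (initializer)
    r_squared: float  # 1 - SS_res/SS_tot on the concentration scale
    residuals: tuple[float, ...]
    n_points_used: int
    accepted: bool  # r_squared >= acceptance threshold


class AssessmentOutcome(BaseModel):
    """Terminal decision-tree result for one PRI at one stage."""

    model_config = ConfigDict(frozen=True)

    pri_id: str
    category: Category
    stage: AssessmentStage
    disposition: Disposition
    metrics: Mapping[str, float] = Field(default_factory=dict)
    rationale: str = ""

    @model_validator(mode="after")
    def _check_category_a(self) -> "AssessmentOutcome":
        if self.category is Category.A:
            if self.stage is not AssessmentStage.step1:
                raise ValueError("Category A PRIs terminate at step 1")
            if self.disposition is not Disposition.no_safety_risk:
                raise ValueError("Category A PRIs pose no safety risk")
        return self


class TestingPlanEntry(BaseModel):
    """In-process testing assignment for a PRI that failed the worst-case
    assessment.  ``assay_lod`` is populated once an assay (or measurement)
    supplies it."""

    model_config = ConfigDict(frozen=True)

    pri_id: str
    test_point: TestPoint
    assay_lod: Optional[float] = Field(default=None, gt=0)  # μg/ml


class MeasurementRecord(BaseModel):
    """One in-process test result used for the Step 2b re-assessment."""

    model_config = ConfigDict(frozen=True)

    pri_id: str
    test_point: TestPoint
    concentration: float = Field(gt=0)  # μg/ml; LOD value when is_lod
    is_lod: bool = False
    protein_concentration: float = Field(gt=0)  # mg/ml at the test point


# --------------------------------------------------------------------------
# Inventory validation
# --------------------------------------------------------------------------

class RecordValidation(BaseModel):
    index: int
    pri_id: Optional[str]
    ok: bool
    messages: tuple[str, ...] = ()


class ValidationReport(BaseModel):
    records: tuple[RecordValidation, ...]

    @property
    def ok(self) -> bool:
        return all(r.ok for r in self.records)

    @property
    def failures(self) -> list[RecordValidation]:
        return [r for r in self.records if not r.ok]


def validate_inventory(records) -> ValidationReport:
    """Validate an inventory, returning per-record diagnostics.

    Accepts a mix of already-constructed :class:`PriRecord` objects and raw
    mappings (as parsed from CSV/JSON).  Validation is total: malformed rows
    produce diagnostics naming the offending field, never exceptions, and
    duplicate ids are rejected.
    """
    results: list[RecordValidation] = []
    seen_ids: dict[str, int] = {}
    for i, raw in enumerate(records):
        messages: list[str] = []
        rid: Optional[str] = None
        if isinstance(raw, PriRecord):
            record: Optional[PriRecord] = raw
            rid = raw.id
        else:
            if isinstance(raw, Mapping) and isinstance(
                raw.get("evidence_codes"), str
            ):
                raw = {
                    **raw,
                    "evidence_codes": frozenset(
                        c.strip()
                        for c in raw["evidence_codes"].split(";")
                        if c.strip()
                    ),
                }
            try:
                record = PriRecord.model_validate(raw)
                rid = record.id
            except Exception as exc:  # pydantic ValidationError or type error
                record = None
                rid = None
                if isinstance(raw, Mapping):
                    rid = str(raw.get("id")) if raw.get("id") else None
                messages.append(_summarize_validation_error(exc))
        if record is not None and rid is not None:
            if rid in seen_ids:
                messages.append(
                    f"duplicate id {rid!r} (first seen at row {seen_ids[rid]})"
                )
            else:
                seen_ids[rid] = i
        results.append(
            RecordValidation(
                index=i, pri_id=rid, ok=not messages, messages=tuple(messages)
            )
        )
    return ValidationReport(records=tuple(results))


def _summarize_validation_error(exc: Exception) -> str:
    try:
        errors = exc.errors()  # type: ignore[attr-defined]
    except AttributeError:
        return str(exc)
    parts = []
    for err in errors:
        loc = ".".join(str(p) for p in err.get("loc", ())) or "record"
        parts.append(f"{loc}: {err.get('msg', 'invalid')}")
    return "; ".join(parts) if parts else str(exc)
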