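"""Dose/toxicology arithmetic: PDE derivation, PRI dose per product dose,
impurity safety factor, and strict limit comparisons.

All functions are pure.  Units follow the package convention
(:mod:`prisafe.core_types`): concentrations in μg/ml (PRI) and mg/ml
(protein), doses in mg (product) and μg (PRI), PDE/TTC in μg/day.
Every pass/fail comparison is a strict inequality — a dose exactly at its
limit fails, which is the conservative reading of "greater than the defined
threshold value".
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_types import DoseContext, ToxicityProfile

UG_PER_MG = 1000.0


class PdeNotDerivableError(ValueError):
    """Raised when neither NOEL nor LOEL is available; callers fall back to
    the impurity-safety-factor path (Category B1)."""


def compute_pde(tox: ToxicityProfile, ctx: DoseContext) -> float:
    """Permitted daily exposure in μg/day.

    PDE = point_of_departure (mg/kg/day) × body_weight (kg) / (F1·F2·F3·F4·F5)

    The NOEL is preferred as point of departure; the LOEL is used only when
    no NOEL exists, and then F5 must exceed 1 to penalise the weaker
    endpoint.

    Raises
    ------
    PdeNotDerivableError
        If the profile carries neither NOEL nor LOEL.
    ValueError
        If the LOEL is used with F5 = 1.
    """
    mf = ctx.modifying_factors
    if tox.noel is not None:
        pod = tox.noel
    elif tox.loel is not None:
        if mf.f5 <= 1.0:
            raise ValueError(
                "PDE from LOEL requires modifying factor F5 > 1; "
                "set it explicitly in the dose context"
            )
        pod = tox.loel
    else:
        raise PdeNotDerivableError("neither NOEL nor LOEL available")
    if pod <= 0:
        raise ValueError("point of departure must be > 0")
    pde_mg_per_day = pod * ctx.body_weight / mf.product
    return pde_mg_per_day * UG_PER_MG


def compute_pri_dose(
    pri_concentration: float, protein_concentration: float, product_dose: float
) -> float:
    """PRI mass (μg) delivered in one product dose.

    (PRI μg/ml ÷ protein mg/ml) × product dose mg — the PRI-to-protein mass
    ratio (μg per mg of protein) scaled by the protein mass administered.
    """
    if pri_concentration < 0:
        raise ValueError("pri_concentration must be >= 0")
    if protein_concentration <= 0:
        raise ValueError("protein_concentration must be > 0")
    if product_dose <= 0:
        raise ValueError("product_dose must be > 0")
    return (pri_concentration / protein_concentration) * product_dose


def compute_isf(toxicity_dose: float, pri_dose: float) -> float:
    """Impurity safety factor: toxicity dose ÷ PRI dose, both in μg on a
    per-patient basis.  Larger is safer."""
    if toxicity_dose <= 0:
        raise ValueError("toxicity_dose must be > 0")
    if pri_dose <= 0:
        raise ValueError("pri_dose must be > 0")
    return toxicity_dose / pri_dose


def toxicity_dose_from_ld50(ld50_mg_per_kg: float, body_weight_kg: float) -> float:
    """Convert an LD50 (mg/kg) to a per-patient toxicity dose in μg."""
    if ld50_mg_per_kg <= 0:
        raise ValueError("ld50 must be > 0")
    if body_weight_kg <= 0:
        raise ValueError("body weight must be > 0")
    return ld50_mg_per_kg * body_weight_kg * UG_PER_MG


def isf_passes(isf: float, threshold: float) -> bool:
    """Strict comparison: the PRI passes only when ISF exceeds the
    configured threshold; a tie fails."""
    if threshold <= 0:
        raise ValueError("isf_threshold must be > 0")
    return isf > threshold


@dataclass(frozen=True)
class MarginResult:
    passed: bool
    margin: float  # limit / dose; > 1 means below the limit


def margin_vs_limit(pri_dose: float, limit: float) -> MarginResult:
    """Compare a daily PRI dose (μg/day) against a safety limit (PDE or
    TTC, μg/day).  Pass requires dose strictly below the limit; the margin
    ratio limit/dose is reported either way."""
    if limit <= 0:
        raise ValueError("limit must be > 0")
    if pri_dose <= 0:
        raise ValueError("pri_dose must be > 0 (LOD substitution upstream)")
    return MarginResult(passed=pri_dose < limit, margin=limit / pri_dose)
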