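"""Clearance-fold accounting across downstream unit operations.

A clearance fold is the ratio of impurity-to-protein mass ratios before and
after a step; folds compose multiplicatively (log-additively) across steps.
When the post-step impurity was below the assay limit of detection the fold
is a lower bound, tracked as a boolean flag rather than interval arithmetic
— the convention in which results are reported as "greater than N-fold".
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core_types import ClearanceMeasurement


class ClearanceResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    step_name: str
    fold: float = Field(gt=0)
    is_lower_bound: bool = False


class BudgetStep(BaseModel):
    model_config = ConfigDict(frozen=True)

    step_name: str
    fold: float = Field(gt=0)


class ClearanceBudget(BaseModel):
    """Assumed minimum per-step clearances and their cumulative product."""

    model_config = ConfigDict(frozen=True)

    steps: tuple[BudgetStep, ...]
    cumulative: float

    @model_validator(mode="after")
    def _check_cumulative(self) -> "ClearanceBudget":
        expected = math.prod(s.fold for s in self.steps) if self.steps else 1.0
        if not math.isclose(self.cumulative, expected, rel_tol=1e-12):
            raise ValueError("cumulative must equal the product of step folds")
        return self


def clearance_fold(m: ClearanceMeasurement) -> ClearanceResult:
    """Impurity clearance across one unit operation:

        (initial PRI / initial protein) / (final PRI / final protein)

    Protein normalisation cancels volume changes (dilution, concentration)
    so the fold reflects genuine removal.  ``final_is_lod`` marks the result
    as a lower bound on the true clearance.
    """
    fold = (m.initial_pri / m.initial_protein) / (m.final_pri / m.final_protein)
    return ClearanceResult(
        step_name=m.step_name, fold=fold, is_lower_bound=m.final_is_lod
    )


def cumulative_clearance(results: Sequence[ClearanceResult]) -> ClearanceResult:
    """Compose per-step folds into an overall clearance (product of folds);
    the result is a lower bound if any contributing step was."""
    if not results:
        raise ValueError("cumulative clearance requires at least one step")
    fold = math.prod(r.fold for r in results)
    return ClearanceResult(
        step_name=" + ".join(r.step_name for r in results),
        fold=fold,
        is_lower_bound=any(r.is_lower_bound for r in results),
    )


_DEFAULT_BUDGET: tuple[tuple[str, float], ...] = (
    ("protein_a", 100.0),
    ("cex_bind_elute", 10.0),
    ("diafiltration", 5.0),
)


def platform_minimum_budget(
    overrides: Optional[dict[str, float]] = None,
    drop: Optional[Iterable[str]] = None,
) -> ClearanceBudget:
    """Minimum clearance a typical mAb downstream platform can be assumed
    to provide: 100-fold from Protein A capture, 10-fold from bind-elute
    cation exchange, 5-fold from diafiltration — 5,000-fold overall.

    Individual steps can be overridden (fold > 0) or dropped.
    """
    overrides = dict(overrides or {})
    dropped = set(drop or ())
    unknown = (set(overrides) | dropped) - {name for name, _ in _DEFAULT_BUDGET}
    if unknown:
        raise ValueError(f"unknown budget steps: {sorted(unknown)}")
    steps = []
    for name, fold in _DEFAULT_BUDGET:
        if name in dropped:
            continue
        value = overrides.get(name, fold)
        if value <= 0:
            raise ValueError(f"budget override for {name} must be > 0")
        steps.append(BudgetStep(step_name=name, fold=value))
    cumulative = math.prod(s.fold for s in steps) if steps else 1.0
    return ClearanceBudget(steps=tuple(steps), cumulative=cumulative)
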