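"""Constant-volume diafiltration washout model.

During constant-retentate-volume diafiltration a freely permeating solute
decays exponentially with the number of diavolumes N:

    C(N) = C0 · exp(−N·S)

where S is the sieving coefficient — the effective transmission of the
solute through the ultrafiltration membrane.  S = 1 is ideal washout;
S < 1 indicates retention (charge attraction to the product protein,
hydrophobic association, or micelles too large for the membrane cut-off);
S slightly above 1 occurs when electrostatic repulsion from the retained
protein enhances expulsion, so fitted values are deliberately not clipped
at 1.

This module provides the forward model, sieving-coefficient estimation from
a measured profile, analytic diavolume planning for a target clearance, and
the surfactant/critical-micelle-concentration guard.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core_types import DiafiltrationProfile, PriRecord, SievingFit

DEFAULT_R2_THRESHOLD = 0.95


class FitError(ValueError):
    """Raised when a profile is too degenerate to support a sieving fit."""


def predict_concentration(c0: float, n: float, s: float) -> float:
    """Retentate concentration (μg/ml) after ``n`` diavolumes at sieving
    coefficient ``s``."""
    if c0 <= 0:
        raise ValueError("c0 must be > 0")
    if n < 0:
        raise ValueError("n must be >= 0")
    if s < 0:
        raise ValueError("s must be >= 0")
    return c0 * math.exp(-n * s)


def clearance_after_dv(n: float, s: float) -> float:
    """Clearance fold after ``n`` diavolumes: exp(n·s) ≥ 1."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if s < 0:
        raise ValueError("s must be >= 0")
    return math.exp(n * s)


def dv_for_target(fold: float, s: float) -> float:
    """Diavolumes needed for a target clearance fold: ln(fold)/s.

    Exact analytic inversion of the washout model, so
    ``clearance_after_dv(dv_for_target(f, s), s) == f`` to floating
    tolerance.
    """
    if fold <= 1:
        raise ValueError("target fold must be > 1")
    if s <= 0:
        raise ValueError(
            "target unreachable: sieving coefficient must be > 0 for any "
            "clearance to accumulate"
        )
    return math.log(fold) / s


def fit_sieving(
    profile: DiafiltrationProfile, r2_threshold: float = DEFAULT_R2_THRESHOLD
) -> SievingFit:
    """Estimate the sieving coefficient from a concentration-vs-diavolume
    profile.

    Nonlinear least squares on the concentration scale for the single
    parameter S of C = C0·exp(−N·S), with C0 fixed at the profile's stated
    initial concentration and the closed-form log-linear slope as the
    initial guess (the log-linear estimate is also reported).  Points flagged
    as at/below the assay LOD are excluded rather than substituted — LOD
    substitution would bias S downward.  The fit is flagged rejected when
    R² (1 − SS_res/SS_tot on the concentration scale) falls below the
    acceptance threshold.
    """
    usable = [p for p in profile.points if not p.is_lod]
    if len(usable) < 3:
        raise FitError(
            f"sieving fit needs at least 3 usable (non-LOD) points, "
            f"got {len(usable)}"
        )
    n = np.array([p.diavolume for p in usable], dtype=float)
    c = np.array([p.concentration for p in usable], dtype=float)
    c0 = profile.c0

    # closed-form initializer: slope of ln(C/C0) vs N through the origin
    denom = float(np.dot(n, n))
    if denom == 0.0:
        raise FitError("profile has no diavolume spread")
    s_loglin = float(-np.dot(n, np.log(c / c0)) / denom)

    def model(nn: np.ndarray, s: float) -> np.ndarray:
        return c0 * np.exp(-nn * s)

    popt, _ = curve_fit(model, n, c, p0=[max(s_loglin, 1e-6)], maxfev=10000)
    s_hat = float(popt[0])

    predicted = model(n, s_hat)
    residuals = c - predicted
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((c - c.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("-inf")

    return SievingFit(
        s=s_hat,
        s_loglinear=s_loglin,
        r_squared=r_squared,
        residuals=tuple(float(r) for r in residuals),
        n_points_used=len(usable),
        accepted=r_squared >= r2_threshold,
    )


class CmcStatus(str, enum.Enum):
    ok = "ok"
    warning = "warning"
    info = "info"


@dataclass(frozen=True)
class CmcCheck:
    status: CmcStatus
    message: str


def cmc_guard(pri: PriRecord, spike_concentration: float) -> CmcCheck:
    """Warn when a surfactant is spiked above its critical micelle
    concentration: micelles exceed the membrane cut-off, so the washout
    model's clearance prediction will not hold."""
    if not pri.surfactant:
        return CmcCheck(CmcStatus.ok, f"{pri.name} is not a surfactant")
    cmc = pri.critical_micelle_concentration
    if cmc is None:
        return CmcCheck(
            CmcStatus.info,
            f"{pri.name} is a surfactant with unknown critical micelle "
            "concentration; poor diafiltration clearance possible",
        )
    if spike_concentration > cmc:
        return CmcCheck(
            CmcStatus.warning,
            f"{pri.name} at {spike_concentration:g} μg/ml exceeds its "
            f"critical micelle concentration ({cmc:g} μg/ml); micelles are "
            "larger than the membrane cut-off and poor clearance is expected",
        )
    return CmcCheck(
        CmcStatus.ok,
        f"{pri.name} at {spike_concentration:g} μg/ml is below its critical "
        f"micelle concentration ({cmc:g} μg/ml)",
    )
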