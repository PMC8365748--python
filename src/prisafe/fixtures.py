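"""Packaged study data and synthetic fixture generators.

Two kinds of data live here:

* Transcribed spiking-study tables — the 13-impurity panel metadata and the
  Protein A / cation-exchange concentration tables, with "< x" entries
  represented as ``value = x`` plus an LOD flag so the lower-bound clearance
  rule applies mechanically.
* Synthetic generators — a worked 105-impurity inventory whose composition
  (96 known-safe, 9 medium-risk with derivable PDE, of which 6 pass the
  worst-case assessment and 3 need in-process testing that then passes at
  the assay LOD) emulates a representative mAb programme, and exponential
  diafiltration decay profiles with configurable sieving coefficient and
  multiplicative lognormal noise.

All generators are seed-deterministic: the same seed yields byte-identical
output.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core_types import (
    ChargeClass,
    DiafiltrationProfile,
    DoseContext,
    EvidenceCode,
    HydrophobicityClass,
    MeasurementRecord,
    ModifyingFactors,
    PriRecord,
    ProfilePoint,
    TestPoint,
    ToxicityProfile,
    UsageStage,
)
from .risk_calculus import compute_pde, compute_pri_dose

# --------------------------------------------------------------------------
# Reference sieving coefficients from the diafiltration spiking studies.
# The tropolone entries conflict in the source data (a printed coefficient
# of 0.7 versus ~8.2 DV for 100-fold clearance, which implies ~0.56); both
# readings are carried under distinct keys and neither is privileged.
# EDTA uses 0.81, inside the reported 0.58–0.83 range and consistent with
# the ~5.7 DV figure for 100-fold clearance.
# --------------------------------------------------------------------------

SIEVING_COEFFICIENTS: dict[str, float] = {
    "copper": 1.09,
    "msx": 1.02,
    "edta": 0.81,
    "caprolactam": 0.6,
    "tropolone_reported": 0.7,
    "tropolone_from_dv": math.log(100) / 8.2,
    "pluronic_f68": 0.11,
}

# Spike levels (μg/ml) for the packaged diafiltration profiles; Pluronic
# F68 uses its documented spike of 450 μg/ml (below the 1,900 μg/ml
# critical micelle concentration), the others a generic 100 μg/ml.
PROFILE_C0: dict[str, float] = {name: 100.0 for name in SIEVING_COEFFICIENTS}
PROFILE_C0["pluronic_f68"] = 450.0


# --------------------------------------------------------------------------
# Transcribed tables
# --------------------------------------------------------------------------

def panel_metadata() -> pd.DataFrame:
    """The 13-impurity clearance-study panel: identity, usage stage,
    molecular weight, physical properties and purpose."""
    rows = [
        ("BME", "upstream", 78.1, "uncharged", False, "support cell growth"),
        ("copper ion", "upstream", 79.5, "positively charged", False,
         "support cell growth and disulfide bond formation"),
        ("caprolactam", "upstream; downstream", 113.2,
         "uncharged and hydrophobic", False, "leachate from containers and tubes"),
        ("dextran sulfate", "upstream", 4000.0, "negatively charged", False,
         "prevent cell aggregation"),
        ("EDTA", "downstream", 292.0, "negatively charged", False,
         "prevent enzyme inhibition and disulfide bond reduction"),
        ("polysaccharide", "upstream", 5000.0, "uncharged", False,
         "support cell growth"),
        ("MTG", "upstream", 108.1, "uncharged", False, "support cell growth"),
        ("MSX", "cell_banking", 180.2, "positively charged", False,
         "support cell selection"),
        ("PEG 8000", "upstream; downstream", 8000.0, "uncharged", False,
         "protein stabilizer"),
        ("Pluronic F68", "upstream; downstream", 8000.0, "uncharged surfactant",
         True, "cell shear protectant and protein stabilizer"),
        ("simethicone", "upstream", 238.5, "uncharged", False, "antifoam"),
        ("Triton X-100", "downstream", 625.0, "nonionic surfactant", True,
         "virus inactivation"),
        ("tropolone", "upstream", 122.1, "hydrophobic", False,
         "support cell growth"),
    ]
    return pd.DataFrame(
        rows,
        columns=["name", "usage", "mw_g_mol", "physical_properties",
                 "surfactant", "purpose"],
    )


def protein_a_clearance_table() -> pd.DataFrame:
    """Protein A spiking-study concentrations (μg/ml).  ``*_lod`` columns
    flag "< x" non-detects stored at the assay LOD value."""
    rows = [
        # name, feed, ft, ft_lod, wash, wash_lod, eluate, eluate_lod
        ("BME", 1005.0, 931.0, False, 1.0, True, 1.0, True),
        ("dextran sulfate", 977.0, 691.0, False, 3.3, False, 0.5, True),
        ("EDTA", 1633.0, 1319.0, False, 0.5, True, 0.5, True),
        ("polysaccharide", 0.47, 0.40, False, 0.00005, True, 0.0001, False),
        ("MTG", 648.0, 623.0, False, 0.8, True, 0.8, True),
        ("MSX", 81.0, 76.0, False, 0.01, True, 0.01, True),
        ("PEG 8000", 16726.0, 15452.0, False, 15.0, True, 15.0, True),
        ("Pluronic F68", 33285.0, 29111.0, False, 2.5, True, 5.0, True),
        ("simethicone", 240.0, 220.0, False, 1.0, True, 1.0, True),
        ("Triton X-100", 10975.0, 9544.0, False, 1.3, False, 0.1, True),
        ("tropolone", 1938.0, 1681.0, False, 1.0, True, 2.8, False),
    ]
    return pd.DataFrame(
        rows,
        columns=["name", "feed", "flow_through", "flow_through_lod",
                 "wash", "wash_lod", "eluate", "eluate_lod"],
    )


def cex_clearance_table() -> pd.DataFrame:
    """Cation-exchange (bind-elute) spiking-study concentrations (μg/ml)."""
    rows = [
        ("BME", 869.0, 651.0, False, 1.0, True),
        ("dextran sulfate", 643.0, 330.0, False, 45.6, False),
        ("EDTA", 615.0, 508.0, False, 0.5, True),
        ("polysaccharide", 0.47, 0.45, False, 0.0006, False),
        ("MTG", 661.0, 520.0, False, 0.8, True),
        ("MSX", 68.0, 56.0, False, 0.01, True),
        ("PEG 8000", 16797.0, 12539.0, False, 20.0, True),
        ("simethicone", 240.0, 220.0, False, 1.3, True),
        ("Triton X-100", 9885.0, 5622.0, False, 94.2, False),
        ("tropolone", 312.0, 211.0, False, 1.8, True),
    ]
    return pd.DataFrame(
        rows,
        columns=["name", "load", "flow_through", "flow_through_lod",
                 "eluate", "eluate_lod"],
    )


def packaged_tables() -> dict[str, pd.DataFrame]:
    """All transcribed tables keyed by a short name."""
    return {
        "panel": panel_metadata(),
        "protein_a": protein_a_clearance_table(),
        "cex": cex_clearance_table(),
    }


def tables_checksum() -> str:
    """Stable digest over the transcribed tables so accidental edits are
    caught by the regression suite."""
    import hashlib

    h = hashlib.sha256()
    for key, df in sorted(packaged_tables().items()):
        h.update(key.encode())
        h.update(df.to_csv(index=False, float_format="%.6g").encode())
    return h.hexdigest()


# --------------------------------------------------------------------------
# Diafiltration profile generator
# --------------------------------------------------------------------------

def generate_diafiltration_profile(
    c0: float,
    s: float,
    n_points: int = 6,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> DiafiltrationProfile:
    """Simulate a washout profile at integer diavolumes 0..n_points.

    Concentrations follow C0·exp(−N·S), multiplied by lognormal noise
    (median 1, shape ``noise_sigma``) when σ > 0.  The N = 0 anchor stays
    noise-free since it defines C0.  σ = 0 gives exact model values.
    """
    if c0 <= 0:
        raise ValueError("c0 must be > 0")
    if s < 0:
        raise ValueError("s must be >= 0")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    points = [ProfilePoint(diavolume=0.0, concentration=c0)]
    for n in range(1, n_points + 1):
        value = c0 * math.exp(-n * s)
        if noise_sigma > 0:
            value *= float(np.exp(rng.normal(0.0, noise_sigma)))
        points.append(ProfilePoint(diavolume=float(n), concentration=value))
    return DiafiltrationProfile(c0=c0, points=tuple(points))


def packaged_sieving_profiles(
    n_points: int = 6, noise_sigma: float = 0.0, seed: int = 0
) -> dict[str, DiafiltrationProfile]:
    """Washout profiles for every reference impurity, generated from its
    documented sieving coefficient and spike level."""
    return {
        name: generate_diafiltration_profile(
            PROFILE_C0[name], s, n_points=n_points,
            noise_sigma=noise_sigma, seed=seed,
        )
        for name, s in SIEVING_COEFFICIENTS.items()
    }


# --------------------------------------------------------------------------
# Worked-example inventory generator
# --------------------------------------------------------------------------

# Known-safe impurity names typical of a CHO-based mAb process: media
# nutrients (metabolites), downstream buffers/salts (GRAS), and approved
# excipients.  Padding names are generated when more are requested.
_SAFE_NAMES: tuple[str, ...] = (
    "L-alanine", "L-arginine", "L-asparagine", "L-aspartic acid",
    "L-cysteine", "L-glutamine", "L-glutamic acid", "glycine",
    "L-histidine", "L-isoleucine", "L-leucine", "L-lysine",
    "L-methionine", "L-phenylalanine", "L-proline", "L-serine",
    "L-threonine", "L-tryptophan", "L-tyrosine", "L-valine",
    "D-glucose", "sodium pyruvate", "choline chloride", "myo-inositol",
    "thiamine", "riboflavin", "niacinamide", "pyridoxine",
    "folic acid", "biotin", "cyanocobalamin", "calcium pantothenate",
    "sodium chloride", "potassium chloride", "calcium chloride",
    "magnesium sulfate", "sodium phosphate", "sodium bicarbonate",
    "sodium acetate", "acetic acid", "tris base", "citric acid",
    "sodium citrate", "sucrose", "trehalose", "sorbitol",
    "polysorbate 80", "polysorbate 20", "L-histidine hydrochloride",
    "zinc sulfate", "ferric nitrate", "sodium selenite",
)

_SAFE_EVIDENCE_CYCLE: tuple[frozenset[EvidenceCode], ...] = (
    frozenset({EvidenceCode.metabolite}),
    frozenset({EvidenceCode.GRAS}),
    frozenset({EvidenceCode.approved_excipient}),
    frozenset({EvidenceCode.metabolite, EvidenceCode.GRAS}),
)

_SAFE_STAGE_CYCLE: tuple[UsageStage, ...] = (
    UsageStage.upstream,
    UsageStage.upstream,
    UsageStage.downstream_pre_CEX,
    UsageStage.formulation,
)


class FixtureSpec(BaseModel):
    """Composition of the synthetic worked-example inventory.

    The default composition — 96 known-safe impurities, 9 medium-risk with
    derivable PDE of which 6 pass worst-case and 3 need testing, all
    testing results non-detect at the assay LOD — emulates a representative
    mAb programme.  Pass/fail placements keep at least ``separation``-fold
    distance from the PDE on either side so dispositions are robust to
    floating-point noise.
    """

    model_config = ConfigDict(frozen=True)

    n_category_a: int = Field(default=96, ge=0)
    n_b2_pass: int = Field(default=6, ge=0)
    n_b2_fail: int = Field(default=3, ge=0)
    product_dose: float = Field(default=500.0, gt=0)  # mg
    product_protein_concentration: float = Field(default=50.0, gt=0)  # mg/ml
    body_weight: float = Field(default=50.0, gt=0)  # kg
    assay_lod: float = Field(default=0.5, gt=0)  # μg/ml
    measurement_protein: float = Field(default=5.0, gt=0)  # mg/ml
    noel_range: tuple[float, float] = (1.0, 5.0)  # mg/kg/day
    separation: float = Field(default=2.0, ge=1.5)
    seed: int = 0

    @model_validator(mode="after")
    def _check_feasible(self) -> "FixtureSpec":
        lo, hi = self.noel_range
        if not (0 < lo <= hi):
            raise ValueError("noel_range must satisfy 0 < low <= high")
        # the LOD-based Step 2b dose must sit below PDE/separation for every
        # possible NOEL draw, otherwise testing can never clear the 3 flagged
        # impurities
        mf = ModifyingFactors()
        min_pde = lo * self.body_weight / mf.product * 1000.0
        lod_dose = (self.assay_lod / self.measurement_protein) * self.product_dose
        if lod_dose * self.separation >= min_pde:
            raise ValueError(
                "infeasible spec: the assay-LOD dose cannot clear the PDE "
                "with the required separation"
            )
        return self


class ExampleDataset(BaseModel):
    model_config = ConfigDict(frozen=True)

    inventory: tuple[PriRecord, ...]
    tox_map: dict[str, ToxicityProfile]
    measurements: dict[str, MeasurementRecord]
    dose_context: DoseContext


def generate_example_inventory(
    spec: Optional[FixtureSpec] = None,
) -> ExampleDataset:
    """Build the worked-example dataset: inventory, toxicity map,
    LOD measurements for the flagged impurities, and the dose context.

    Composition parameters are data on the :class:`FixtureSpec`, not
    hard-coded in the decision engine; the same seed yields identical
    output.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    ctx = DoseContext(
        product_dose=spec.product_dose,
        product_protein_concentration=spec.product_protein_concentration,
        body_weight=spec.body_weight,
    )

    inventory: list[PriRecord] = []
    tox_map: dict[str, ToxicityProfile] = {}

    for i in range(spec.n_category_a):
        name = (
            _SAFE_NAMES[i]
            if i < len(_SAFE_NAMES)
            else f"media component {i - len(_SAFE_NAMES) + 1:02d}"
        )
        inventory.append(
            PriRecord(
                id=f"A{i + 1:03d}",
                name=name,
                usage_stage=_SAFE_STAGE_CYCLE[i % len(_SAFE_STAGE_CYCLE)],
                usage_concentration=float(np.round(rng.uniform(1, 5000), 1)),
                evidence_codes=_SAFE_EVIDENCE_CYCLE[i % len(_SAFE_EVIDENCE_CYCLE)],
            )
        )

    b2_names = [
        "antifoam C emulsion", "poloxamer shear protectant",
        "selection reagent", "chelating agent", "reducing agent",
        "surfactant stabilizer", "antibiotic residue", "inducer compound",
        "leachable stabilizer", "process additive", "buffer modifier",
    ]
    n_b2 = spec.n_b2_pass + spec.n_b2_fail
    protein_at_stage = ctx.product_protein_concentration
    for j in range(n_b2):
        pid = f"B{j + 1:03d}"
        noel = float(np.round(rng.uniform(*spec.noel_range), 2))
        tox = ToxicityProfile(noel=noel)
        pde = compute_pde(tox, ctx)  # μg/day
        fails = j >= spec.n_b2_pass
        # place the worst-case dose a random >= separation factor from PDE
        factor = float(rng.uniform(spec.separation, 2 * spec.separation))
        target_dose = pde * factor if fails else pde / factor
        usage = target_dose * protein_at_stage / ctx.product_dose
        record = PriRecord(
            id=pid,
            name=b2_names[j % len(b2_names)],
            usage_stage=UsageStage.upstream,
            usage_concentration=float(usage),
            evidence_codes=frozenset({EvidenceCode.medium_toxicity}),
        )
        # guard against drift between placement arithmetic and the engine
        dose = compute_pri_dose(usage, protein_at_stage, ctx.product_dose)
        if fails and dose < pde * spec.separation:
            raise ValueError(f"infeasible placement for {pid}")
        if not fails and dose > pde / spec.separation:
            raise ValueError(f"infeasible placement for {pid}")
        inventory.append(record)
        tox_map[pid] = tox

    measurements = {
        rec.id: MeasurementRecord(
            pri_id=rec.id,
            test_point=TestPoint.viral_filtration_pool,
            concentration=spec.assay_lod,
            is_lod=True,
            protein_concentration=spec.measurement_protein,
        )
        for rec in inventory[spec.n_category_a + spec.n_b2_pass:]
    }

    return ExampleDataset(
        inventory=tuple(inventory),
        tox_map=tox_map,
        measurements=measurements,
        dose_context=ctx,
    )
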