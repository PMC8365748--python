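"""File formats and report rendering.

Formats are deliberately plain: inventories as CSV (evidence codes
semicolon-delimited) with an equivalent JSON form, toxicity maps as JSON,
measurements and diafiltration profiles as CSV, configuration as YAML, and
workflow reports as JSON (machine) or Markdown (human).  Unit conversion,
where needed, happens here and only here — internal values always carry the
package's fixed units.

The report JSON schema is published via :func:`report_json_schema` and
round-trip validation is done by re-parsing into the report model.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from .core_types import (
    DiafiltrationProfile,
    DoseContext,
    MeasurementRecord,
    ModifyingFactors,
    PriRecord,
    ProfilePoint,
    TestPoint,
    ToxicityProfile,
    UsageStage,
)
from .decision_engine import WorkflowReport

PathLike = Union[str, Path]

_INVENTORY_COLUMNS = [
    "id", "name", "molecular_weight", "charge_class", "hydrophobicity_class",
    "surfactant", "critical_micelle_concentration", "usage_stage",
    "usage_concentration", "evidence_codes",
]


# --------------------------------------------------------------------------
# Inventory
# --------------------------------------------------------------------------

def inventory_to_frame(records: Sequence[PriRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = r.model_dump()
        d["evidence_codes"] = ";".join(sorted(c.value for c in r.evidence_codes))
        d["charge_class"] = r.charge_class.value
        d["hydrophobicity_class"] = r.hydrophobicity_class.value
        d["usage_stage"] = r.usage_stage.value
        rows.append(d)
    return pd.DataFrame(rows, columns=_INVENTORY_COLUMNS)


def _row_to_record_dict(row: Mapping[str, Any]) -> dict[str, Any]:
    d = dict(row)
    codes = d.get("evidence_codes")
    if isinstance(codes, str):
        d["evidence_codes"] = frozenset(
            c.strip() for c in codes.split(";") if c.strip()
        )
    elif codes is None or (isinstance(codes, float) and pd.isna(codes)):
        d["evidence_codes"] = frozenset()
    for key in ("molecular_weight", "critical_micelle_concentration"):
        if key in d and (d[key] is None or (isinstance(d[key], float) and pd.isna(d[key])) or d[key] == ""):
            d[key] = None
    return d


def write_inventory_csv(records: Sequence[PriRecord], path: PathLike) -> None:
    # %.17g preserves float round-trip precision
    inventory_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def read_inventory_rows(path: PathLike) -> list[dict[str, Any]]:
    """Raw inventory rows for pre-construction validation."""
    df = pd.read_csv(path, float_precision="round_trip")
    return [_row_to_record_dict(row) for row in df.to_dict(orient="records")]


def read_inventory_csv(path: PathLike) -> list[PriRecord]:
    return [PriRecord.model_validate(row) for row in read_inventory_rows(path)]


def write_inventory_json(records: Sequence[PriRecord], path: PathLike) -> None:
    payload = [
        {**r.model_dump(mode="json"),
         "evidence_codes": sorted(c.value for c in r.evidence_codes)}
        for r in records
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_inventory_json(path: PathLike) -> list[PriRecord]:
    payload = json.loads(Path(path).read_text())
    return [PriRecord.model_validate(item) for item in payload]


# --------------------------------------------------------------------------
# Toxicity map
# --------------------------------------------------------------------------

def write_tox_map_json(
    tox_map: Mapping[str, ToxicityProfile], path: PathLike
) -> None:
    payload = {k: v.model_dump(mode="json") for k, v in sorted(tox_map.items())}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_tox_map_json(path: PathLike) -> dict[str, ToxicityProfile]:
    payload = json.loads(Path(path).read_text())
    return {k: ToxicityProfile.model_validate(v) for k, v in payload.items()}


# --------------------------------------------------------------------------
# Measurements
# --------------------------------------------------------------------------

_MEASUREMENT_COLUMNS = [
    "pri_id", "test_point", "concentration", "is_lod", "protein_concentration",
]


def write_measurements_csv(
    measurements: Mapping[str, MeasurementRecord], path: PathLike
) -> None:
    rows = [
        {**m.model_dump(), "test_point": m.test_point.value}
        for _, m in sorted(measurements.items())
    ]
    pd.DataFrame(rows, columns=_MEASUREMENT_COLUMNS).to_csv(path, index=False)


def read_measurements_csv(path: PathLike) -> dict[str, MeasurementRecord]:
    df = pd.read_csv(path)
    out: dict[str, MeasurementRecord] = {}
    for row in df.to_dict(orient="records"):
        m = MeasurementRecord.model_validate(row)
        out[m.pri_id] = m
    return out


# --------------------------------------------------------------------------
# Diafiltration profiles
# --------------------------------------------------------------------------

def write_profile_csv(profile: DiafiltrationProfile, path: PathLike) -> None:
    pd.DataFrame(
        [{"diavolume": p.diavolume, "concentration": p.concentration,
          "is_lod": p.is_lod} for p in profile.points]
    ).to_csv(path, index=False)


def read_profile_csv(path: PathLike) -> DiafiltrationProfile:
    df = pd.read_csv(path)
    if "is_lod" not in df.columns:
        df["is_lod"] = False
    points = tuple(
        ProfilePoint(
            diavolume=float(r["diavolume"]),
            concentration=float(r["concentration"]),
            is_lod=bool(r["is_lod"]),
        )
        for r in df.to_dict(orient="records")
    )
    return DiafiltrationProfile(c0=points[0].concentration, points=points)


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

def load_config_yaml(path: PathLike) -> DoseContext:
    """Build a :class:`DoseContext` from a YAML file.

    Recognised keys: product_dose, product_protein_concentration,
    body_weight, ttc, isf_threshold, f1..f5,
    stage_protein_concentrations (stage name → mg/ml).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    factors = ModifyingFactors(
        **{k: raw[k] for k in ("f1", "f2", "f3", "f4", "f5") if k in raw}
    )
    stage_map = {
        UsageStage(k): float(v)
        for k, v in (raw.get("stage_protein_concentrations") or {}).items()
    }
    kwargs: dict[str, Any] = {
        k: raw[k]
        for k in ("product_dose", "product_protein_concentration",
                  "body_weight", "ttc", "isf_threshold")
        if k in raw
    }
    return DoseContext(
        modifying_factors=factors,
        stage_protein_concentrations=stage_map,
        **kwargs,
    )


# --------------------------------------------------------------------------
# Reports
# --------------------------------------------------------------------------

def report_json_schema() -> dict[str, Any]:
    """JSON schema for the workflow report."""
    return WorkflowReport.model_json_schema()


def validate_report_json(payload: Union[str, Mapping[str, Any]]) -> WorkflowReport:
    """Parse and validate a serialized report; raises on schema violation."""
    if isinstance(payload, str):
        payload = json.loads(payload)
    return WorkflowReport.model_validate(payload)


def render_report(
    report: WorkflowReport,
    fmt: str = "json",
    path: Optional[PathLike] = None,
    header: Optional[Mapping[str, Any]] = None,
) -> str:
    """Render a workflow report as JSON or Markdown; optionally write it.

    ``header`` (seed, config file, version …) is embedded for
    reproducibility.
    """
    if fmt == "json":
        payload = report.model_dump(mode="json")
        if header:
            payload = {"header": dict(header), **payload}
        text = json.dumps(payload, indent=2)
    elif fmt in ("md", "markdown"):
        text = _render_markdown(report, header)
    else:
        raise ValueError(f"unknown report format: {fmt!r}")
    if path is not None:
        Path(path).write_text(text)
    return text


def _render_markdown(
    report: WorkflowReport, header: Optional[Mapping[str, Any]]
) -> str:
    lines = ["# PRI safety risk assessment report", ""]
    if header:
        lines.append("## Run metadata")
        lines.append("")
        for k, v in header.items():
            lines.append(f"- {k}: {v}")
        lines.append("")
    lines.append(f"Inventory size: {report.n_pris}")
    lines.append("")
    lines.append("## Category tally")
    lines.append("")
    lines.append("| Category | Count |")
    lines.append("| --- | --- |")
    for cat, count in report.category_counts.items():
        lines.append(f"| {cat} | {count} |")
    lines.append("")
    lines.append("## Disposition tally")
    lines.append("")
    lines.append("| Disposition | Count |")
    lines.append("| --- | --- |")
    for disp, count in report.disposition_counts.items():
        lines.append(f"| {disp} | {count} |")
    lines.append("")
    if report.testing_plan:
        lines.append("## Testing plan")
        lines.append("")
        lines.append("| PRI | Test point | Assay LOD (μg/ml) |")
        lines.append("| --- | --- | --- |")
        for entry in report.testing_plan:
            lod = "" if entry.assay_lod is None else f"{entry.assay_lod:g}"
            lines.append(f"| {entry.pri_id} | {entry.test_point.value} | {lod} |")
        lines.append("")
    if report.unmatched_measurement_ids:
        lines.append("## Unmatched measurement ids")
        lines.append("")
        for mid in report.unmatched_measurement_ids:
            lines.append(f"- {mid}")
        lines.append("")
    lines.append("## Per-PRI outcomes")
    lines.append("")
    lines.append("| PRI | Category | Stage | Disposition | Rationale |")
    lines.append("| --- | --- | --- | --- | --- |")
    for o in report.outcomes:
        lines.append(
            f"| {o.pri_id} | {o.category.value} | {o.stage.value} "
            f"| {o.disposition.value} | {o.rationale} |"
        )
    lines.append("")
    lines.append("## Configuration snapshot")
    lines.append("")
    lines.append("```json")
    lines.append(json.dumps(dict(report.config_snapshot), indent=2, default=str))
    lines.append("```")
    return "\n".join(lines)
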