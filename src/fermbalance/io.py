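"""CSV/config ingestion, validation and report rendering.

All tabular inputs are plain CSV with a required header; schemas are strict —
unknown columns are rejected by name so a typo cannot silently drop an
analyte from the carbon balance.
"""

from __future__ import annotations

import csv
import io as _stdio
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .carbon_balance import (
    FermentationSummary,
    ProductProfile,
    SubstrateSpec,
    THEORETICAL_ETHANOL_PER_GLUCOSE,
)
from .copy_number import CopyEstimate, CoverageRecord, CoverageTable
from .enzyme_activity import AssayMeasurement
from .errors import ValidationError

PRODUCT_ANALYTES = ("glucose", "maltose", "glycerol", "acetic_acid", "ethanol")
PRODUCT_COLUMNS = ("strain", "time_h") + PRODUCT_ANALYTES
COVERAGE_COLUMNS = ("sample", "gene", "avg_coverage", "role")
ASSAY_COLUMNS = (
    "strain",
    "substrate_form",
    "substrate_load_pct",
    "temperature_c",
    "assay_kind",
    "glucose_umol",
    "minutes",
    "volume_ml",
)

SUBSTRATE_KEYS = (
    "starch_as_is",
    "starch_dry",
    "added_glucose",
    "hydrolysis_factor",
    "theoretical_factor",
)


def _read_csv(path: str | Path, required: Sequence[str], optional: Sequence[str] = ()):
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: file has no header") from None
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    unknown = [c for c in frame.columns if c not in (*required, *optional)]
    if unknown:
        raise ValidationError(f"{path}: unknown column(s) {unknown}")
    return frame


def _number(raw: str, path, row: int, column: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise ValidationError(
            f"{path}: row {row}, column {column!r}: malformed number {raw!r}"
        ) from None


def read_products(path: str | Path) -> list[ProductProfile]:
    """Read a product-concentration CSV into validated profiles.

    Schema: strain,time_h,glucose,maltose,glycerol,acetic_acid,ethanol[,co2].
    """
    frame = _read_csv(path, PRODUCT_COLUMNS, optional=("co2",))
    profiles: list[ProductProfile] = []
    analytes = PRODUCT_ANALYTES + (("co2",) if "co2" in frame.columns else ())
    for i, row in frame.iterrows():
        conc = {a: _number(row[a], path, i + 2, a) for a in analytes}
        for a, v in conc.items():
            if v < 0:
                raise ValidationError(
                    f"{path}: row {i + 2}, column {a!r}: negative concentration {v}"
                )
        profiles.append(
            ProductProfile(
                conc,
                time_h=_number(row["time_h"], path, i + 2, "time_h"),
                strain_label=str(row["strain"]),
            )
        )
    return profiles


def write_products(profiles: Sequence[ProductProfile], path: str | Path) -> None:
    """Write profiles in the products CSV schema (co2 column only if present)."""
    has_co2 = any("co2" in p.concentrations for p in profiles)
    columns = PRODUCT_COLUMNS + (("co2",) if has_co2 else ())
    rows = []
    for p in profiles:
        row: dict[str, object] = {"strain": p.strain_label, "time_h": p.time_h}
        for a in columns[2:]:
            row[a] = p.get(a)
        rows.append(row)
    pd.DataFrame(rows, columns=list(columns)).to_csv(path, index=False)


def read_coverage(path: str | Path) -> dict[str, CoverageTable]:
    """Read a coverage CSV into one CoverageTable per sample label."""
    frame = _read_csv(path, COVERAGE_COLUMNS)
    tables: dict[str, list[CoverageRecord]] = {}
    for i, row in frame.iterrows():
        cov = _number(row["avg_coverage"], path, i + 2, "avg_coverage")
        tables.setdefault(str(row["sample"]), []).append(
            CoverageRecord(str(row["gene"]), cov, str(row["role"]))
        )
    return {
        sample: CoverageTable(tuple(records), sample)
        for sample, records in tables.items()
    }


def read_assays(path: str | Path) -> list[AssayMeasurement]:
    """Read raw assay measurements (µmol glucose, minutes, ml supernatant)."""
    frame = _read_csv(path, ASSAY_COLUMNS)
    out = []
    for i, row in frame.iterrows():
        out.append(
            AssayMeasurement(
                glucose_released=_number(row["glucose_umol"], path, i + 2, "glucose_umol"),
                duration=_number(row["minutes"], path, i + 2, "minutes"),
                volume=_number(row["volume_ml"], path, i + 2, "volume_ml"),
                substrate_form=str(row["substrate_form"]),
                substrate_load=_number(
                    row["substrate_load_pct"], path, i + 2, "substrate_load_pct"
                ),
                temperature=_number(row["temperature_c"], path, i + 2, "temperature_c"),
                assay_kind=str(row["assay_kind"]),
                strain_label=str(row["strain"]),
            )
        )
    return out


def read_substrate(path: str | Path) -> tuple[SubstrateSpec, float]:
    """Read a key-value (YAML) substrate config.

    Returns the substrate spec and the theoretical ethanol-per-glucose factor
    (defaulting to the package convention when absent).
    """
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, Mapping):
        raise ValidationError(f"{path}: expected key-value pairs")
    unknown = [k for k in raw if k not in SUBSTRATE_KEYS]
    if unknown:
        raise ValidationError(f"{path}: unknown key(s) {unknown}")
    for key in ("starch_as_is", "starch_dry"):
        if key not in raw:
            raise ValidationError(f"{path}: missing required key {key!r}")
    spec = SubstrateSpec(
        starch_as_is=float(raw["starch_as_is"]),
        starch_dry=float(raw["starch_dry"]),
        added_glucose=float(raw.get("added_glucose", 0.0)),
        hydrolysis_factor=float(raw.get("hydrolysis_factor", 1.11)),
    )
    factor = float(raw.get("theoretical_factor", THEORETICAL_ETHANOL_PER_GLUCOSE))
    return spec, factor


@dataclass
class Report:
    """Combined analysis report plus provenance of how it was produced."""

    fermentation: list[FermentationSummary] = field(default_factory=list)
    copy_estimates: list[tuple[str, CopyEstimate]] = field(default_factory=list)
    activities: list[tuple[AssayMeasurement, float]] = field(default_factory=list)
    provenance: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.provenance.setdefault("package_version", __version__)

    def to_dict(self) -> dict[str, object]:
        return {
            "provenance": self.provenance,
            "fermentation": [
                {
                    "strain": s.strain_label,
                    "time_h": s.time_h,
                    "glucose_equivalent": s.glucose_equivalent,
                    "available_carbon": s.available_carbon,
                    "product_carbon": s.product_carbon,
                    "carbon_conversion_pct": s.carbon_conversion_pct,
                    "ethanol_yield_pct": s.ethanol_yield_pct,
                    "ethanol_productivity": s.productivity,
                    "total_products": s.total_products,
                }
                for s in self.fermentation
            ],
            "copy_number": [
                {
                    "sample": sample,
                    "gene": e.gene,
                    "ratio": e.ratio,
                    "copies": e.copies,
                    "housekeeping_mean": e.housekeeping_mean,
                }
                for sample, e in self.copy_estimates
            ],
            "activity": [
                {
                    "strain": m.strain_label,
                    "substrate_form": m.substrate_form,
                    "substrate_load_pct": m.substrate_load,
                    "temperature_c": m.temperature,
                    "assay_kind": m.assay_kind,
                    "glucose_umol": m.glucose_released,
                    "minutes": m.duration,
                    "volume_ml": m.volume,
                    "activity_u_ml": u,
                }
                for m, u in self.activities
            ],
        }


_FERM_TSV_COLUMNS = (
    "strain",
    "time_h",
    "glucose_equivalent",
    "total_products",
    "carbon_conversion_pct",
    "ethanol_yield_pct",
    "ethanol_productivity",
)


def render_report(report: Report, format: str = "tsv") -> str:
    """Render a report as TSV (rounded per table conventions) or JSON (lossless)."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True)
    if format != "tsv":
        raise ValidationError(f"unknown report format {format!r}")
    buf = _stdio.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    if report.fermentation:
        writer.writerow(_FERM_TSV_COLUMNS)
        for s in report.fermentation:
            row = s.as_report_row()
            writer.writerow(
                [
                    row["strain"],
                    row["time_h"],
                    f"{row['glucose_equivalent']:.1f}",
                    f"{row['total_products']:.2f}",
                    row["carbon_conversion_pct"],
                    row["ethanol_yield_pct"],
                    ""
                    if row["ethanol_productivity"] is None
                    else f"{row['ethanol_productivity']:.2f}",
                ]
            )
    if report.copy_estimates:
        writer.writerow(["sample", "gene", "ratio", "copies", "housekeeping_mean"])
        for sample, e in report.copy_estimates:
            writer.writerow(
                [sample, e.gene, f"{e.ratio:.2f}", e.copies, f"{e.housekeeping_mean:.2f}"]
            )
    if report.activities:
        writer.writerow(
            ["strain", "substrate_form", "temperature_c", "assay_kind", "activity_u_ml"]
        )
        for m, u in report.activities:
            writer.writerow(
                [m.strain_label, m.substrate_form, m.temperature, m.assay_kind, f"{u:.2f}"]
            )
    if not (report.fermentation or report.copy_estimates or report.activities):
        writer.writerow(_FERM_TSV_COLUMNS)
    return buf.getvalue()


def parse_report_json(text: str) -> Report:
    """Parse the JSON rendering back into a Report (lossless round trip)."""
    raw = json.loads(text)
    ferm = [
        FermentationSummary(
            strain_label=r["strain"],
            time_h=r["time_h"],
            glucose_equivalent=r["glucose_equivalent"],
            available_carbon=r["available_carbon"],
            product_carbon=r["product_carbon"],
            carbon_conversion_pct=r["carbon_conversion_pct"],
            ethanol_yield_pct=r["ethanol_yield_pct"],
            productivity=r["ethanol_productivity"],
            total_products=r["total_products"],
        )
        for r in raw.get("fermentation", [])
    ]
    copies = [
        (
            r["sample"],
            CopyEstimate(r["gene"], r["ratio"], r["copies"], r["housekeeping_mean"]),
        )
        for r in raw.get("copy_number", [])
    ]
    activities = [
        (
            AssayMeasurement(
                glucose_released=r["glucose_umol"],
                duration=r["minutes"],
                volume=r["volume_ml"],
                substrate_form=r["substrate_form"],
                substrate_load=r["substrate_load_pct"],
                temperature=r["temperature_c"],
                assay_kind=r["assay_kind"],
                strain_label=r["strain"],
            ),
            r["activity_u_ml"],
        )
        for r in raw.get("activity", [])
    ]
    report = Report(fermentation=ferm, copy_estimates=copies, activities=activities)
    report.provenance = raw.get("provenance", {})
    return report
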