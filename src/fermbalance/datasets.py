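"""Packaged fixtures: the published product, coverage and activity tables.

These are the printed summary tables of a raw-corn-starch CBP fermentation
study (laboratory-strain screen, industrial-strain fermentations with and
without enzyme supplementation, per-gene sequencing coverages, amylase
activities), shipped as CSV package data so analyses and tests run without
any external download. ``*_reported`` tables carry the computed rows exactly
as printed, for cross-checking recomputed values.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .carbon_balance import ProductProfile, SubstrateSpec
from .copy_number import CoverageTable
from .io import read_coverage, read_products, read_substrate

#: 200 g/l raw corn starch as-is, 183.3 g/l dry weight, 5 g/l added glucose.
REFERENCE_SUBSTRATE = SubstrateSpec(
    starch_as_is=200.0, starch_dry=183.3, added_glucose=5.0
)

#: Elapsed fermentation hours behind every packaged product table.
REFERENCE_ELAPSED_H = 192.0


def _data_path(name: str) -> Path:
    return Path(str(resources.files("fermbalance").joinpath("data", name)))


def laboratory_products() -> list[ProductProfile]:
    """Product profiles of the seven laboratory-strain fermentations (192 h, 30 C)."""
    return read_products(_data_path("table2_products.csv"))


def laboratory_reported() -> pd.DataFrame:
    """Printed totals, conversions, yields and productivities for the lab strains."""
    return pd.read_csv(_data_path("table2_reported.csv"))


def industrial_products() -> list[ProductProfile]:
    """Product profiles of the twelve industrial fermentations (192 h, 30/37 C,
    varying enzyme-cocktail dosage)."""
    return read_products(_data_path("table6_products.csv"))


def industrial_reported() -> pd.DataFrame:
    """Printed computed rows for the industrial fermentations."""
    return pd.read_csv(_data_path("table6_reported.csv"))


def sequencing_coverage() -> dict[str, CoverageTable]:
    """Per-gene average coverage for the two sequenced industrial strains."""
    return read_coverage(_data_path("table5_coverage.csv"))


def coverage_reported() -> pd.DataFrame:
    """Printed copy-number ratios and integer calls for the target genes."""
    return pd.read_csv(_data_path("table5_reported.csv"))


def amylase_activities() -> pd.DataFrame:
    """Printed amylase activities (U ml^-1) by strain, substrate, temperature
    and detection assay."""
    return pd.read_csv(_data_path("table4_activities.csv"))


def reference_substrate_config() -> Path:
    """Path to the packaged substrate config (usable with the analyze CLI)."""
    return _data_path("substrate_reference.yaml")


def reference_substrate() -> SubstrateSpec:
    spec, _ = read_substrate(reference_substrate_config())
    return spec
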