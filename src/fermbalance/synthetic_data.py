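"""Synthetic fermentation time courses and coverage tables with known truth.

The generators exist so every analysis stage can be exercised end to end with
a known ground truth:

* Fermentation: substrate carbon is hydrolysed along a logistic curve h(t)
  and the hydrolysed carbon is split among the products by fixed partition
  fractions; ethanol and CO2 share their joint fraction 2:1 on a carbon basis
  (two of the three glucose-derived carbons end up in ethanol, one in CO2).
  By construction the estimated carbon conversion of a noiseless profile at
  time t equals 100*h(t) exactly, which makes the carbon-balance statistic
  testable against a known value. Gaussian measurement noise is added per
  analyte and clipped at zero. CO2 is not emitted — like the real assay, it
  is left to be inferred from ethanol downstream.

* Coverage: each gene's average depth is the mean of ``gene_length``
  independent Poisson draws with mean ``base_depth * copies`` (copies = 1 for
  the housekeeping panel), the counting model under which depth is
  proportional to copy number.

Both generators are deterministic given their seed; all draws flow from a
single numpy Generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .carbon_balance import (
    CarbonTable,
    ProductProfile,
    SubstrateSpec,
    available_carbon,
    glucose_equivalent,
)
from .copy_number import DEFAULT_HOUSEKEEPING_PANEL, CoverageRecord, CoverageTable
from .errors import ValidationError

#: Reference substrate loading: 200 g/l raw corn starch as-is (183.3 g/l dry)
#: plus 5 g/l free glucose.
REFERENCE_SUBSTRATE = SubstrateSpec(
    starch_as_is=200.0, starch_dry=183.3, added_glucose=5.0
)

#: Default carbon partition, patterned on a near-complete 192-h industrial
#: fermentation: almost all hydrolysed carbon in ethanol+CO2, a few percent in
#: glycerol, traces in acetate and residual sugars.
DEFAULT_PARTITION: Mapping[str, float] = {
    "ethanol_co2": 0.97,
    "glycerol": 0.02,
    "acetic_acid": 0.005,
    "glucose": 0.003,
    "maltose": 0.002,
}

_PARTITION_KEYS = tuple(DEFAULT_PARTITION)


def logistic_hydrolysis(t: float, midpoint_h: float, steepness: float) -> float:
    """Hydrolysed fraction h(t) in [0, 1] as a logistic in time."""
    return 1.0 / (1.0 + math.exp(-steepness * (t - midpoint_h)))


@dataclass(frozen=True)
class FermentationSimConfig:
    """Generative parameters for a synthetic fermentation time course.

    midpoint_h / steepness parameterize the logistic hydrolysis curve; the
    defaults put half-hydrolysis at 48 h (the observed lag before conversion
    picks up) and near-complete hydrolysis by 192 h. noise_sd is the additive
    Gaussian measurement error per analyte in g l^-1.
    """

    substrate: SubstrateSpec = REFERENCE_SUBSTRATE
    midpoint_h: float = 48.0
    steepness: float = 0.05  # per hour
    partition: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PARTITION)
    )
    noise_sd: float = 0.5
    timepoints: Sequence[float] = (24.0, 48.0, 72.0, 96.0, 120.0, 144.0, 168.0, 192.0)
    seed: int = 0
    strain_label: str = "synthetic"

    def __post_init__(self) -> None:
        if set(self.partition) != set(_PARTITION_KEYS):
            raise ValidationError(
                f"partition must have exactly the keys {_PARTITION_KEYS}"
            )
        if any(v < 0 for v in self.partition.values()):
            raise ValidationError("partition fractions must be >= 0")
        total = sum(self.partition.values())
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(f"partition fractions must sum to 1, got {total}")
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if any(t <= 0 for t in self.timepoints):
            raise ValidationError("timepoints must be positive hours")
        if any(
            b <= a for a, b in zip(self.timepoints, list(self.timepoints)[1:])
        ):
            raise ValidationError("timepoints must be strictly increasing")


def simulate_fermentation(cfg: FermentationSimConfig) -> list[ProductProfile]:
    """Generate one noisy product profile per configured time point.

    At each time t the hydrolysed carbon h(t) * C_avail is split by the
    partition fractions and converted to g l^-1 via the default carbon table;
    the ethanol+CO2 fraction is divided 2:1 (carbon basis) and only the
    ethanol half-pair is emitted (CO2 inferred downstream).
    """
    table = CarbonTable.default()
    rng = np.random.default_rng(cfg.seed)
    c_avail = available_carbon(glucose_equivalent(cfg.substrate))

    def grams(analyte: str, mol_c: float) -> float:
        atoms, mass = table.entries[analyte]
        return mol_c * mass / atoms

    profiles: list[ProductProfile] = []
    for t in cfg.timepoints:
        c_hyd = logistic_hydrolysis(t, cfg.midpoint_h, cfg.steepness) * c_avail
        conc = {
            "ethanol": grams("ethanol", cfg.partition["ethanol_co2"] * c_hyd * 2 / 3),
            "glycerol": grams("glycerol", cfg.partition["glycerol"] * c_hyd),
            "acetic_acid": grams("acetic_acid", cfg.partition["acetic_acid"] * c_hyd),
            "glucose": grams("glucose", cfg.partition["glucose"] * c_hyd),
            "maltose": grams("maltose", cfg.partition["maltose"] * c_hyd),
        }
        if cfg.noise_sd > 0:
            noise = rng.normal(0.0, cfg.noise_sd, size=len(conc))
            conc = {
                k: max(0.0, v + e) for (k, v), e in zip(conc.items(), noise)
            }
        profiles.append(
            ProductProfile(conc, time_h=t, strain_label=cfg.strain_label)
        )
    return profiles


@dataclass(frozen=True)
class CoverageSimConfig:
    """Generative parameters for a synthetic per-gene coverage table."""

    true_copies: Mapping[str, int] = field(
        default_factory=lambda: {"temA": 4, "temG_Opt": 7}
    )
    base_depth: float = 34.0
    gene_length: int = 10_000
    housekeeping_genes: Sequence[str] = DEFAULT_HOUSEKEEPING_PANEL
    seed: int = 0
    sample_label: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.base_depth > 0:
            raise ValidationError(f"base_depth must be > 0, got {self.base_depth}")
        if self.gene_length < 1:
            raise ValidationError(f"gene_length must be >= 1, got {self.gene_length}")
        if not self.true_copies:
            raise ValidationError("true_copies must name at least one target gene")
        for gene, k in self.true_copies.items():
            if int(k) != k or k < 1:
                raise ValidationError(
                    f"{gene}: copy number must be a positive integer, got {k}"
                )
        if not self.housekeeping_genes:
            raise ValidationError("at least one housekeeping gene is required")


def simulate_coverage(cfg: CoverageSimConfig) -> CoverageTable:
    """Generate a coverage table whose target depths scale with copy number."""
    rng = np.random.default_rng(cfg.seed)

    def avg_depth(mean: float) -> float:
        return float(rng.poisson(mean, size=cfg.gene_length).mean())

    records = [
        CoverageRecord(gene, avg_depth(cfg.base_depth * copies), "target")
        for gene, copies in cfg.true_copies.items()
    ]
    records += [
        CoverageRecord(gene, avg_depth(cfg.base_depth), "housekeeping")
        for gene in cfg.housekeeping_genes
    ]
    return CoverageTable(tuple(records), cfg.sample_label)
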