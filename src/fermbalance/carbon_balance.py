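"""Stoichiometric carbon-balance accounting for starch-to-ethanol fermentations.

A consolidated-bioprocessing (CBP) fermentation converts raw starch into a
small set of carbon-bearing products measurable by HPLC — residual glucose and
maltose, glycerol, acetic acid and ethanol — plus CO2, which is not measured
but follows ethanol 1:1 on a molar basis (one CO2 per ethanol in the
fermentative pathway). Comparing the carbon recovered in those products with
the carbon available from the substrate gives the *estimated carbon
conversion*, the headline statistic of a raw-starch fermentation:

    conversion (%) = 100 * sum_i( c_i * a_i / M_i ) / C_avail

where c_i is the concentration (g l^-1) of analyte i, a_i its carbon atoms per
molecule, M_i its molar mass, and C_avail the mol carbon per litre in the
fully hydrolysed substrate. Complete hydrolysis of starch yields 1.11 g
glucose per g dry starch (water is added across each glycosidic bond), so a
loading of 183.3 g l^-1 dry starch plus 5 g l^-1 free glucose supplies a
glucose equivalent of 208.5 g l^-1 and 6.95 mol carbon l^-1.

Ethanol performance is additionally reported as a percent of the theoretical
yield (0.50 g ethanol per g glucose by default) and as a volumetric
productivity (g l^-1 h^-1 over the elapsed fermentation time).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Sequence

from .errors import CarbonBalanceWarning, ValidationError

logger = logging.getLogger(__name__)

#: Glucose gained per gram of dry starch on complete hydrolysis (water uptake).
STARCH_HYDROLYSIS_FACTOR = 1.11

#: Default maximum ethanol mass per gram of glucose for percent-of-theoretical
#: yield. The stoichiometric maximum is 0.511 g/g; 0.50 g/g is the convention
#: adopted here (configurable in every yield call).
THEORETICAL_ETHANOL_PER_GLUCOSE = 0.50

#: Threshold above which a conversion is flagged as physically inconsistent.
CONVERSION_FLAG_PCT = 105.0

_DEFAULT_CARBON_ENTRIES: Mapping[str, tuple[int, float]] = MappingProxyType(
    {
        "maltose": (12, 342.0),
        "glucose": (6, 180.0),
        "glycerol": (3, 92.0),
        "acetic_acid": (2, 60.0),
        "ethanol": (2, 46.0),
        "co2": (1, 44.0),
    }
)


def _half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class CarbonTable:
    """Per-analyte (carbon atoms, molar mass g/mol) constants driving the balance."""

    entries: Mapping[str, tuple[int, float]] = field(
        default_factory=lambda: _DEFAULT_CARBON_ENTRIES
    )

    def __post_init__(self) -> None:
        for name, (atoms, mass) in self.entries.items():
            if atoms < 1:
                raise ValidationError(f"{name}: carbon_atoms must be >= 1, got {atoms}")
            if mass <= 0:
                raise ValidationError(f"{name}: molar_mass must be > 0, got {mass}")
        object.__setattr__(self, "entries", MappingProxyType(dict(self.entries)))

    @classmethod
    def default(cls) -> "CarbonTable":
        return cls()

    def __contains__(self, analyte: str) -> bool:
        return analyte in self.entries

    def carbon_mol(self, analyte: str, grams_per_l: float) -> float:
        """mol carbon per litre contributed by ``grams_per_l`` of ``analyte``."""
        try:
            atoms, mass = self.entries[analyte]
        except KeyError:
            raise ValidationError(f"analyte {analyte!r} not in carbon table") from None
        return grams_per_l * atoms / mass


@dataclass(frozen=True)
class ProductProfile:
    """Measured product concentrations (g l^-1) at one strain/time point.

    ``co2`` may be omitted; it is then inferred from ethanol wherever needed.
    """

    concentrations: Mapping[str, float]
    time_h: float | None = None
    strain_label: str = ""

    def __post_init__(self) -> None:
        for name, value in self.concentrations.items():
            if not math.isfinite(value) or value < 0:
                raise ValidationError(
                    f"concentration of {name!r} must be finite and >= 0, got {value}"
                )
        if self.time_h is not None and self.time_h <= 0:
            raise ValidationError(f"time_h must be > 0, got {self.time_h}")
        object.__setattr__(
            self, "concentrations", MappingProxyType(dict(self.concentrations))
        )

    def get(self, analyte: str, default: float = 0.0) -> float:
        return self.concentrations.get(analyte, default)

    def with_co2(self, table: CarbonTable | None = None) -> "ProductProfile":
        """Return a profile whose ``co2`` is present, inferred if absent."""
        if "co2" in self.concentrations:
            return self
        conc = dict(self.concentrations)
        conc["co2"] = co2_from_ethanol(self.get("ethanol"))
        return ProductProfile(conc, self.time_h, self.strain_label)


@dataclass(frozen=True)
class SubstrateSpec:
    """Substrate loading of one fermentation.

    Parameters
    ----------
    starch_as_is : g l^-1 starch as weighed in (moisture included).
    starch_dry : g l^-1 dry starch; basis for the glucose equivalent.
    added_glucose : g l^-1 free glucose added to the medium.
    hydrolysis_factor : g glucose per g dry starch on complete hydrolysis.
    """

    starch_as_is: float
    starch_dry: float
    added_glucose: float = 0.0
    hydrolysis_factor: float = STARCH_HYDROLYSIS_FACTOR

    def __post_init__(self) -> None:
        if not 0 < self.starch_dry <= self.starch_as_is:
            raise ValidationError(
                "require 0 < starch_dry <= starch_as_is, got "
                f"dry={self.starch_dry}, as_is={self.starch_as_is}"
            )
        if self.added_glucose < 0:
            raise ValidationError(f"added_glucose must be >= 0, got {self.added_glucose}")
        if self.hydrolysis_factor <= 1:
            raise ValidationError(
                f"hydrolysis_factor must exceed 1, got {self.hydrolysis_factor}"
            )


@dataclass(frozen=True)
class FermentationSummary:
    """All derived quantities for one time point, kept at full precision.

    ``as_report_row`` applies the reporting conventions (integer percents,
    two-decimal concentrations and productivities).
    """

    strain_label: str
    time_h: float | None
    glucose_equivalent: float  # g/l
    available_carbon: float  # mol C / l
    product_carbon: float  # mol C / l
    carbon_conversion_pct: float
    ethanol_yield_pct: float
    productivity: float | None  # g/l/h
    total_products: float  # g/l

    def as_report_row(self) -> dict[str, object]:
        return {
            "strain": self.strain_label,
            "time_h": self.time_h,
            "glucose_equivalent": round(self.glucose_equivalent, 1),
            "total_products": round(self.total_products, 2),
            "carbon_conversion_pct": _half_away(self.carbon_conversion_pct),
            "ethanol_yield_pct": _half_away(self.ethanol_yield_pct),
            "ethanol_productivity": (
                None if self.productivity is None else round(self.productivity, 2)
            ),
        }


def glucose_equivalent(substrate: SubstrateSpec) -> float:
    """Glucose released by complete hydrolysis plus any added glucose (g l^-1)."""
    return substrate.starch_dry * substrate.hydrolysis_factor + substrate.added_glucose


def available_carbon(glucose_equiv: float) -> float:
    """mol carbon l^-1 in the fully hydrolysed substrate (6 C per 180 g glucose)."""
    if not glucose_equiv > 0:
        raise ValidationError(f"glucose_equiv must be > 0, got {glucose_equiv}")
    return glucose_equiv * 6.0 / 180.0


def co2_from_ethanol(ethanol: float) -> float:
    """CO2 (g l^-1) implied by the ethanol titre: one mol CO2 per mol ethanol.

    Full precision; report rounded to two decimals.
    """
    if ethanol < 0:
        raise ValidationError(f"ethanol must be >= 0, got {ethanol}")
    return ethanol * 44.0 / 46.0


def product_carbon(profile: ProductProfile, table: CarbonTable | None = None) -> float:
    """mol carbon l^-1 recovered in the products (CO2 inferred if absent)."""
    table = table or CarbonTable.default()
    full = profile.with_co2(table)
    for analyte in full.concentrations:
        if analyte not in table:
            raise ValidationError(f"analyte {analyte!r} not in carbon table")
    return sum(
        table.carbon_mol(analyte, grams)
        for analyte, grams in full.concentrations.items()
    )


def carbon_conversion(
    profile: ProductProfile,
    substrate: SubstrateSpec,
    table: CarbonTable | None = None,
) -> float:
    """Estimated carbon conversion (%): product carbon over available carbon.

    Returned at full precision; table convention is to report the nearest
    integer. Values above ``CONVERSION_FLAG_PCT`` trigger a
    :class:`CarbonBalanceWarning` (flagged, never clipped).
    """
    avail = available_carbon(glucose_equivalent(substrate))
    pct = 100.0 * product_carbon(profile, table) / avail
    if pct > CONVERSION_FLAG_PCT:
        warnings.warn(
            f"carbon conversion {pct:.1f}% exceeds {CONVERSION_FLAG_PCT}%: "
            "products contain more carbon than the substrate supplied "
            f"(strain {profile.strain_label!r})",
            CarbonBalanceWarning,
            stacklevel=2,
        )
    return pct


def ethanol_yield_pct(
    ethanol: float,
    glucose_equiv: float,
    theoretical_factor: float = THEORETICAL_ETHANOL_PER_GLUCOSE,
) -> float:
    """Ethanol titre as a percent of the theoretical yield on available glucose."""
    if not glucose_equiv > 0:
        raise ValidationError(f"glucose_equiv must be > 0, got {glucose_equiv}")
    if ethanol < 0:
        raise ValidationError(f"ethanol must be >= 0, got {ethanol}")
    if not theoretical_factor > 0:
        raise ValidationError(
            f"theoretical_factor must be > 0, got {theoretical_factor}"
        )
    return 100.0 * (ethanol / glucose_equiv) / theoretical_factor


def ethanol_productivity(ethanol: float, elapsed: float) -> float:
    """Volumetric productivity (g l^-1 h^-1) over the elapsed time from inoculation."""
    if not elapsed > 0:
        raise ValidationError(f"elapsed hours must be > 0, got {elapsed}")
    if ethanol < 0:
        raise ValidationError(f"ethanol must be >= 0, got {ethanol}")
    return ethanol / elapsed


def total_products(profile: ProductProfile, table: CarbonTable | None = None) -> float:
    """Sum of the product concentrations (g l^-1), CO2 inferred if absent."""
    full = profile.with_co2(table)
    return sum(full.concentrations.values())


def fold_change(numerator: float, denominator: float) -> float:
    """Simple ratio of two quantities; report to one decimal."""
    if not denominator > 0:
        raise ValidationError(f"denominator must be > 0, got {denominator}")
    return numerator / denominator


def summarize(
    timecourse: Sequence[ProductProfile],
    substrate: SubstrateSpec,
    table: CarbonTable | None = None,
    theoretical_factor: float = THEORETICAL_ETHANOL_PER_GLUCOSE,
) -> list[FermentationSummary]:
    """Full-precision summaries for a time course of product profiles.

    Time points must be strictly increasing; productivity at each point uses
    that point's elapsed hours from inoculation.
    """
    table = table or CarbonTable.default()
    # a time course is per strain; a cross-sectional table (many strains at a
    # shared endpoint) is fine, repeated times within one strain are not
    by_strain: dict[str, list[float]] = {}
    for p in timecourse:
        if p.time_h is not None:
            by_strain.setdefault(p.strain_label, []).append(p.time_h)
    for label, times in by_strain.items():
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError(
                f"time points for {label!r} must be strictly increasing, got {times}"
            )
    logger.debug("carbon table in effect: %s", dict(table.entries))

    ge = glucose_equivalent(substrate)
    avail = available_carbon(ge)
    out: list[FermentationSummary] = []
    for profile in timecourse:
        full = profile.with_co2(table)
        pc = product_carbon(full, table)
        out.append(
            FermentationSummary(
                strain_label=profile.strain_label,
                time_h=profile.time_h,
                glucose_equivalent=ge,
                available_carbon=avail,
                product_carbon=pc,
                carbon_conversion_pct=carbon_conversion(full, substrate, table),
                ethanol_yield_pct=ethanol_yield_pct(
                    full.get("ethanol"), ge, theoretical_factor
                ),
                productivity=(
                    None
                    if profile.time_h is None
                    else ethanol_productivity(full.get("ethanol"), profile.time_h)
                ),
                total_products=total_products(full, table),
            )
        )
    return out
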