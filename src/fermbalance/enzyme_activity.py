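"""Amylase activity unit conversion.

One activity unit (U) is the amount of enzyme that releases one micromole of
glucose per minute under the assay conditions; activities are expressed per
millilitre of culture supernatant. Assays differ in substrate form (raw
granular vs autoclaved soluble starch), substrate loading, temperature and
detection chemistry (reducing-sugar assays see all reducing ends; glucose-kit
assays see free glucose only) — all carried as labels on the measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

from .carbon_balance import fold_change
from .errors import ValidationError

_SUBSTRATE_FORMS = ("raw", "soluble")
_ASSAY_KINDS = ("reducing_sugar", "glucose_only")


@dataclass(frozen=True)
class AssayMeasurement:
    """One endpoint amylase assay read.

    glucose_released : µmol glucose (or glucose equivalents) released.
    duration : assay minutes.
    volume : ml supernatant assayed.
    """

    glucose_released: float
    duration: float
    volume: float
    substrate_form: str = "raw"
    substrate_load: float | None = None  # % w/v
    temperature: float | None = None  # degrees C
    assay_kind: str = "glucose_only"
    strain_label: str = ""

    def __post_init__(self) -> None:
        if self.glucose_released < 0:
            raise ValidationError(
                f"glucose_released must be >= 0, got {self.glucose_released}"
            )
        if not self.duration > 0:
            raise ValidationError(f"duration must be > 0, got {self.duration}")
        if not self.volume > 0:
            raise ValidationError(f"volume must be > 0, got {self.volume}")
        if self.substrate_form not in _SUBSTRATE_FORMS:
            raise ValidationError(
                f"substrate_form must be one of {_SUBSTRATE_FORMS}, "
                f"got {self.substrate_form!r}"
            )
        if self.assay_kind not in _ASSAY_KINDS:
            raise ValidationError(
                f"assay_kind must be one of {_ASSAY_KINDS}, got {self.assay_kind!r}"
            )


def activity_units(m: AssayMeasurement) -> float:
    """Activity in U ml^-1 supernatant: µmol glucose / min / ml.

    Linear endpoint formula; full precision, report to two decimals.
    """
    return m.glucose_released / m.duration / m.volume


def activity_fold(a: float, b: float) -> float:
    """Fold difference between two activities (a over b); report to one decimal."""
    return fold_change(a, b)
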