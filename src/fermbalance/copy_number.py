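"""Transgene copy-number estimation from sequencing coverage ratios.

When an expression cassette is integrated at multiple chromosomal sites
(e.g. delta-integration into Ty retrotransposon LTRs in S. cerevisiae), the
number of integrated copies is reflected in whole-genome sequencing read
depth: a gene present in k copies accumulates roughly k times the depth of a
single-copy locus. The estimator here normalizes a target gene's average
coverage by the mean coverage of a panel of constitutively single-copy
housekeeping genes (ACT1, ALG9, PGK1, TFC1 by default):

    copies ~= coverage(target) / mean(coverage(housekeeping panel))

The fractional ratio is always reported alongside the nearest-integer call
(ties rounded away from zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .carbon_balance import _half_away
from .errors import UnknownGeneError, ValidationError

#: Single-copy reference genes used to normalize read depth.
DEFAULT_HOUSEKEEPING_PANEL: tuple[str, ...] = ("ACT1", "ALG9", "PGK1", "TFC1")

_ROLES = ("target", "housekeeping")


@dataclass(frozen=True)
class CoverageRecord:
    gene: str
    avg_coverage: float
    role: str  # "target" | "housekeeping"

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValidationError(f"role must be one of {_ROLES}, got {self.role!r}")
        if self.avg_coverage < 0:
            raise ValidationError(
                f"{self.gene}: avg_coverage must be >= 0, got {self.avg_coverage}"
            )
        if self.role == "housekeeping" and self.avg_coverage <= 0:
            raise ValidationError(
                f"{self.gene}: housekeeping coverage must be > 0, got {self.avg_coverage}"
            )


@dataclass(frozen=True)
class CoverageTable:
    """Per-gene average sequencing depth for one sample."""

    records: tuple[CoverageRecord, ...]
    sample_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        roles = {r.role for r in self.records}
        if "target" not in roles or "housekeeping" not in roles:
            raise ValidationError(
                "coverage table needs at least one target and one housekeeping record"
            )
        seen: set[str] = set()
        for r in self.records:
            if r.gene in seen:
                raise ValidationError(f"duplicate gene {r.gene!r} in coverage table")
            seen.add(r.gene)

    @classmethod
    def from_mappings(
        cls,
        targets: Mapping[str, float],
        housekeeping: Mapping[str, float],
        sample_label: str = "",
    ) -> "CoverageTable":
        records = [CoverageRecord(g, c, "target") for g, c in targets.items()]
        records += [CoverageRecord(g, c, "housekeeping") for g, c in housekeeping.items()]
        return cls(tuple(records), sample_label)

    def targets(self) -> tuple[CoverageRecord, ...]:
        return tuple(r for r in self.records if r.role == "target")

    def housekeeping(self) -> tuple[CoverageRecord, ...]:
        return tuple(r for r in self.records if r.role == "housekeeping")

    def coverage(self, gene: str) -> float:
        for r in self.records:
            if r.gene == gene:
                return r.avg_coverage
        raise UnknownGeneError(gene)


@dataclass(frozen=True)
class CopyEstimate:
    """Copy-number call for one target gene.

    ``ratio`` is the fractional estimate (target depth over the normalizing
    depth); ``copies`` is its nearest-integer rounding, ties away from zero.
    """

    gene: str
    ratio: float
    copies: int
    housekeeping_mean: float


def housekeeping_mean(
    table: CoverageTable, weights: Mapping[str, float] | None = None
) -> float:
    """Mean coverage of the housekeeping panel (unweighted by default).

    Per-gene weights (e.g. gene lengths) may be supplied; missing genes get
    weight zero.
    """
    hk = table.housekeeping()
    if weights is None:
        return float(np.mean([r.avg_coverage for r in hk]))
    w = np.array([weights.get(r.gene, 0.0) for r in hk], dtype=float)
    if w.sum() <= 0:
        raise ValidationError("housekeeping weights sum to zero")
    c = np.array([r.avg_coverage for r in hk], dtype=float)
    return float(np.average(c, weights=w))


def estimate_copy_number(
    table: CoverageTable,
    gene: str,
    denominator: float | None = None,
    weights: Mapping[str, float] | None = None,
) -> CopyEstimate:
    """Estimate integrated copies of ``gene`` from its coverage ratio.

    Parameters
    ----------
    denominator : optional explicit normalizing depth (e.g. a genome-wide
        scaffold average). Defaults to the housekeeping-panel mean.
    """
    record = next((r for r in table.targets() if r.gene == gene), None)
    if record is None:
        raise UnknownGeneError(gene)
    hk_mean = housekeeping_mean(table, weights)
    denom = hk_mean if denominator is None else denominator
    if not denom > 0:
        raise ValidationError(f"normalizing coverage must be > 0, got {denom}")
    ratio = record.avg_coverage / denom
    return CopyEstimate(gene, ratio, _half_away(ratio), hk_mean)


def estimate_all(
    table: CoverageTable,
    denominator: float | None = None,
    weights: Mapping[str, float] | None = None,
) -> list[CopyEstimate]:
    """Copy estimates for every target gene in the table."""
    return [
        estimate_copy_number(table, r.gene, denominator, weights)
        for r in table.targets()
    ]


def depth_to_coverage(depths: Sequence[int] | Iterable[int]) -> float:
    """Average coverage from a per-position depth vector."""
    arr = np.asarray(list(depths) if not isinstance(depths, np.ndarray) else depths)
    if arr.size == 0:
        raise ValidationError("depth vector is empty")
    if (arr < 0).any():
        raise ValidationError("depths must be non-negative")
    return float(arr.mean())
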