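"""Temporal accuracy: annual burned-area percentages and their aggregation.

The annual percentage detected by a product is the ratio of its total burned
pixels to the reference's total burned pixels (a ratio of totals, not of the
spatial overlap):

    P_year(%) = 100 * sum_i BAP_year(i) / sum_i BAR_year(i)

and the multi-year summary is the weighted average

    Pbar(%) = 100 * (sum_years sum_i BAP) / (sum_years sum_i BAR),

which equals the reference-area-weighted mean of the annual percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateInputError, EmptyReferenceError, GridMismatchError
from .grid import CATEGORY_NAMES, BurnGrid, FireEvent

__all__ = [
    "AnnualRecord",
    "annual_percentage",
    "weighted_average_percentage",
    "determination_coefficient",
    "categorize_fires",
    "CategorySummary",
]


@dataclass(frozen=True)
class AnnualRecord:
    """Reference and product burned areas for one year."""

    year: int
    BAR_ha: float
    BAP_ha: float

    def __post_init__(self) -> None:
        if self.BAR_ha < 0 or self.BAP_ha < 0:
            raise ValueError("burned areas must be non-negative")

    @property
    def P_pct(self) -> float:
        """Annual burned-area percentage (undefined when BAR_ha = 0)."""
        if self.BAR_ha == 0:
            raise EmptyReferenceError(f"year {self.year}: reference area is zero")
        return 100.0 * self.BAP_ha / self.BAR_ha


def annual_percentage(product: BurnGrid, reference: BurnGrid) -> float:
    """Percentage of the reference burned area detected by the product map."""
    if product.spec != reference.spec:
        raise GridMismatchError("product and reference grids differ")
    n_ref = reference.burned_pixels
    if n_ref == 0:
        raise EmptyReferenceError("annual percentage undefined: empty reference")
    return 100.0 * product.burned_pixels / n_ref


def weighted_average_percentage(records: Iterable[AnnualRecord]) -> float:
    """Multi-year percentage: ratio of summed product to summed reference area.

    Years with exactly zero reference area are excluded from both sums.
    """
    bar = bap = 0.0
    for rec in records:
        if rec.BAR_ha == 0:
            continue
        bar += rec.BAR_ha
        bap += rec.BAP_ha
    if bar == 0:
        raise EmptyReferenceError("no year has a non-zero reference area")
    return 100.0 * bap / bar


def determination_coefficient(x: Sequence[float], y: Sequence[float]) -> float:
    """R^2 between two annual series: the squared Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be one-dimensional and of equal length")
    if len(x) < 3:
        raise DegenerateInputError("need at least 3 points for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("series with zero variance have no correlation")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


@dataclass(frozen=True)
class CategorySummary:
    """Counts and area shares of fires by size class."""

    counts: dict[str, int]
    area_ha: dict[str, float]
    area_share_pct: dict[str, float]
    total_fires: int
    total_area_ha: float


def categorize_fires(events: Iterable[FireEvent]) -> CategorySummary:
    """Tally fires and burned-area shares per size class."""
    counts = {name: 0 for name in CATEGORY_NAMES}
    area = {name: 0.0 for name in CATEGORY_NAMES}
    for ev in events:
        counts[ev.category] += 1
        area[ev.category] += ev.area_ha
    total_area = sum(area.values())
    shares = {
        name: (100.0 * a / total_area if total_area else 0.0)
        for name, a in area.items()
    }
    return CategorySummary(
        counts=counts,
        area_ha=area,
        area_share_pct=shares,
        total_fires=sum(counts.values()),
        total_area_ha=total_area,
    )
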