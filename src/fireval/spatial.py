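"""Spatial accuracy: pixel-level confusion matrix and derived error metrics.

For a binary burned/non-burned classification against reference data the
confusion matrix counts are (classified map in rows, reference in columns):

    n11 true burned      n12 false burned     -> n1c (classified burned)
    n21 false non-burned n22 true non-burned  -> n2c
    n1r (reference burned)  n2r               -> n

and the derived metrics are

    OA = (n11 + n22) / n         overall accuracy
    S  = n11 / n1r               sensitivity (producer's accuracy), S = 1 - OE
    Sp = n22 / n2r               specificity (rate of true non-burned)
    CE = n12 / n1c               commission error
    OE = n21 / n1r               omission error

The burned class is heavily outnumbered by the unburned class in wildfire
mapping, so OA and Sp are near 1 regardless of skill; validation therefore
rests on CE and OE.  Because the two errors have different denominators they
are combined into a total error weighted by the detected fraction P:

    TE (ha) = CE * BAP + OE * BAR = (CE * P + OE) * BAR
    TE      = TE(ha) / BAR = CE * P + OE          (P = BAP / BAR, a fraction)

TE may legitimately exceed 1 (e.g. CE = OE = 1 with P > 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import GridMismatchError
from .grid import BurnGrid

__all__ = [
    "ConfusionCounts",
    "AccuracyMetrics",
    "confusion_counts",
    "metrics",
    "total_error",
    "total_error_ha",
    "weighted_error_summary",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Cell counts of the 2x2 burned/non-burned confusion matrix."""

    n11: int
    n12: int
    n21: int
    n22: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n12, self.n21, self.n22) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n1c(self) -> int:
        """Pixels classified burned."""
        return self.n11 + self.n12

    @property
    def n2c(self) -> int:
        return self.n21 + self.n22

    @property
    def n1r(self) -> int:
        """Pixels burned in the reference."""
        return self.n11 + self.n21

    @property
    def n2r(self) -> int:
        return self.n12 + self.n22

    @property
    def n(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22


@dataclass(frozen=True)
class AccuracyMetrics:
    OA: float
    S: float
    Sp: float
    CE: float
    OE: float


def confusion_counts(product: BurnGrid, reference: BurnGrid) -> ConfusionCounts:
    """Count the four agreement cells between a product and a reference map."""
    if product.spec != reference.spec:
        raise GridMismatchError("product and reference grids differ")
    p = product.values.astype(bool)
    r = reference.values.astype(bool)
    return ConfusionCounts(
        n11=int(np.count_nonzero(p & r)),
        n12=int(np.count_nonzero(p & ~r)),
        n21=int(np.count_nonzero(~p & r)),
        n22=int(np.count_nonzero(~p & ~r)),
    )


def metrics(c: ConfusionCounts) -> AccuracyMetrics:
    """Derive OA, S, Sp, CE, OE from confusion counts.

    Empty-class conventions: an empty detection (n1c = 0) has CE = 0; an
    empty reference (n1r = 0) has OE = 0 and S = 1 (with a warning, as it
    indicates a degenerate comparison).  An all-burned reference (n2r = 0)
    has Sp = 1.
    """
    if c.n == 0:
        raise ValueError("empty confusion matrix")
    CE = c.n12 / c.n1c if c.n1c else 0.0
    if c.n1r:
        OE = c.n21 / c.n1r
        S = c.n11 / c.n1r
    else:
        warnings.warn("reference has no burned pixels; OE set to 0", stacklevel=2)
        OE, S = 0.0, 1.0
    Sp = c.n22 / c.n2r if c.n2r else 1.0
    OA = (c.n11 + c.n22) / c.n
    return AccuracyMetrics(OA=OA, S=S, Sp=Sp, CE=CE, OE=OE)


def total_error(CE: float, OE: float, P: float) -> float:
    """Weighted total error TE = CE * P + OE (all arguments as fractions)."""
    if CE < 0 or OE < 0 or P < 0:
        raise ValueError("CE, OE and P must be non-negative")
    return CE * P + OE


def total_error_ha(CE: float, OE: float, BAP_ha: float, BAR_ha: float) -> float:
    """Total error in hectares: CE * BAP + OE * BAR."""
    if CE < 0 or OE < 0 or BAP_ha < 0 or BAR_ha < 0:
        raise ValueError("arguments must be non-negative")
    return CE * BAP_ha + OE * BAR_ha


@dataclass(frozen=True)
class ErrorSummary:
    """Multi-year error summary with reference-area weights."""

    CE: float
    OE: float
    P: float
    TE: float


def weighted_error_summary(
    years: list[tuple[float, float, float, float]],
) -> ErrorSummary:
    """Summarize per-year (CE, OE, BAP_ha, BAR_ha) rows over a period.

    CE and OE are averaged with weights proportional to each year's share of
    the total reference burned area; the all-years detected fraction P is the
    ratio of summed product to summed reference area; and the all-years TE is
    recomputed from the summary values via TE = CE * P + OE.
    """
    bar_total = sum(row[3] for row in years)
    if bar_total == 0:
        raise ValueError("total reference burned area is zero")
    w = [row[3] / bar_total for row in years]
    CE = sum(wi * row[0] for wi, row in zip(w, years))
    OE = sum(wi * row[1] for wi, row in zip(w, years))
    P = sum(row[2] for row in years) / bar_total
    return ErrorSummary(CE=CE, OE=OE, P=P, TE=total_error(CE, OE, P))
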