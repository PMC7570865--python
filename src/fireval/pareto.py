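"""Pareto boundaries of burned-area classification at degraded resolution.

A coarse pixel holding a burned-area fraction f must be labelled entirely
Burned or Not Burned by any strict binary classifier.  Labelling it Burned
commits an error of (1 - f) pixel-areas; labelling it Not Burned omits f.
Sweeping the minimum-fraction threshold p over [0, 1] therefore traces the
lowest (CE, OE) pairs achievable at that resolution — the Pareto boundary
(PB).  Errors on the PB are attributable solely to sub-pixel fragmentation
of the burned area, not to any detection algorithm.

The area under the PB (AUPB), integrated by the trapezoidal rule with CE as
the independent variable, is a scalar fragmentation measure: 0 when every
coarse pixel is pure, increasing as mixed pixels proliferate.  Regressing a
product's total error on the annual AUPB quantifies how much of its error
budget the resolution itself explains.

Both errors here are *area-based* (fractions of pixel area): classifying a
mixed pixel as Burned counts (1 - f) of one pixel as commission.  A
pixel-count bookkeeping would agree only for pure pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, EmptyReferenceError
from .grid import FractionGrid

__all__ = [
    "ParetoCurve",
    "threshold_classify",
    "pareto_boundary",
    "aupb",
    "fit_te_vs_aupb",
    "distance_to_boundary",
    "RegressionResult",
]


@dataclass(frozen=True)
class ParetoCurve:
    """Pareto boundary: thresholds and their (CE, OE) pairs, CE ascending.

    ``p`` holds, for each surviving point, the smallest threshold that
    attains it.  After Pareto filtering OE is strictly decreasing in CE, so
    the boundary is a proper function OE(CE) and the trapezoidal integral
    (``aupb``) is well defined.
    """

    p: np.ndarray
    CE: np.ndarray
    OE: np.ndarray
    resolution_m: float
    aupb: float

    def __len__(self) -> int:
        return len(self.CE)


def _positive_fractions(frac: FractionGrid) -> np.ndarray:
    values = frac.values
    if frac.padded_mask is not None:
        values = values[~frac.padded_mask]
    return values.ravel()


def threshold_classify(frac: FractionGrid, p: float) -> tuple[float, float]:
    """Area-based (CE, OE) of the strict binary classification at threshold p.

    The classified-burned set is ``{f >= p}`` for p > 0 and ``{f > 0}`` for
    p = 0 (so fully unburned pixels are never classified Burned).  CE is the
    committed area per classified pixel; OE is the omitted fraction of the
    total burned area.  An empty classification has CE = 0.
    """
    if not 0 <= p <= 1:
        raise ValueError("threshold p must lie in [0, 1]")
    v = _positive_fractions(frac)
    total = v.sum()
    if total == 0:
        raise EmptyReferenceError("fraction grid has no burned area; OE undefined")
    burned = v >= p if p > 0 else v > 0
    nb = int(burned.sum())
    CE = float((1.0 - v[burned]).sum() / nb) if nb else 0.0
    OE = float(v[~burned].sum() / total)
    return CE, OE


def _sweep(values: np.ndarray, thresholds: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorized threshold sweep via prefix sums over descending fractions."""
    pos = np.sort(values[values > 0])  # ascending positives
    m = len(pos)
    total = pos.sum()
    desc = pos[::-1]
    prefix = np.concatenate([[0.0], np.cumsum(desc)])  # prefix[k] = sum of top-k
    # k(p): number of pixels classified burned at threshold p
    k = np.where(
        thresholds > 0,
        m - np.searchsorted(pos, thresholds, side="left"),
        m,
    )
    counts = k.astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        CE = np.where(counts > 0, (counts - prefix[counts]) / np.maximum(counts, 1), 0.0)
    OE = 1.0 - prefix[counts] / total
    return CE, OE


def _pareto_filter(
    p: np.ndarray, CE: np.ndarray, OE: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deduplicate and drop Pareto-dominated points; sort by ascending CE."""
    order = np.lexsort((p, OE, CE))
    keep: list[int] = []
    for i in order:
        if keep and OE[i] >= OE[keep[-1]]:
            continue  # dominated (or duplicate): CE is >= the last kept point's
        keep.append(int(i))
    idx = np.array(keep, dtype=int)
    return p[idx], CE[idx], OE[idx]


def pareto_boundary(
    frac: FractionGrid, n_steps: int | str = 101
) -> ParetoCurve:
    """Construct the Pareto boundary of a fraction grid by threshold sweep.

    ``n_steps`` equidistant thresholds in [0, 1] are evaluated (default 101);
    ``n_steps="exact"`` sweeps every distinct positive fraction instead
    (plus p = 1 when no pixel is fully burned, anchoring the empty
    classification).  Duplicate and Pareto-dominated (CE, OE) pairs are
    removed, leaving a strictly decreasing OE(CE).
    """
    v = _positive_fractions(frac)
    if v.sum() == 0:
        raise EmptyReferenceError("fraction grid has no burned area")
    if isinstance(n_steps, str):
        if n_steps != "exact":
            raise ValueError("n_steps must be an integer >= 2 or 'exact'")
        thresholds = np.unique(v[v > 0])
        if thresholds[-1] < 1.0:
            thresholds = np.append(thresholds, 1.0)
    else:
        if n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        thresholds = np.linspace(0.0, 1.0, n_steps)
    CE, OE = _sweep(v, thresholds)
    p, CE, OE = _pareto_filter(thresholds, CE, OE)
    area = aupb_points(CE, OE)
    return ParetoCurve(
        p=p, CE=CE, OE=OE, resolution_m=frac.spec.pixel_size, aupb=area
    )


def aupb_points(CE: Sequence[float], OE: Sequence[float]) -> float:
    """Trapezoidal area under a CE-sorted (CE, OE) point set; 0 for one point."""
    CE = np.asarray(CE, dtype=float)
    OE = np.asarray(OE, dtype=float)
    if len(CE) == 0:
        raise ValueError("need at least one point")
    if len(CE) == 1:
        return 0.0
    return float(np.sum((OE[1:] + OE[:-1]) / 2.0 * np.diff(CE)))


def aupb(curve: ParetoCurve) -> float:
    """Area under the Pareto boundary of a constructed curve."""
    return aupb_points(curve.CE, curve.OE)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


def fit_te_vs_aupb(pairs: Sequence[tuple[float, float]]) -> RegressionResult:
    """OLS regression of annual total error on annual AUPB.

    ``pairs`` are (AUPB, TE) tuples, one per year; at least 3 are required
    and the AUPB values must not be constant.
    """
    pairs = list(pairs)
    if len(pairs) < 3:
        raise DegenerateInputError("need at least 3 (AUPB, TE) pairs")
    x = np.array([a for a, _ in pairs], dtype=float)
    y = np.array([t for _, t in pairs], dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateInputError("AUPB values are constant; slope undefined")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=len(pairs),
    )


def distance_to_boundary(CE: float, OE: float, curve: ParetoCurve) -> float:
    """Minimum Euclidean distance from a product's (CE, OE) to the PB curve.

    The boundary is treated as the piecewise-linear curve through its points
    (a single-point curve degenerates to that point).  A qualitative gauge of
    how much of a map's error exceeds the resolution-imposed floor.
    """
    px = np.asarray(curve.CE, dtype=float)
    py = np.asarray(curve.OE, dtype=float)
    if len(px) == 1:
        return float(np.hypot(CE - px[0], OE - py[0]))
    ax, ay = px[:-1], py[:-1]
    bx, by = px[1:], py[1:]
    dx, dy = bx - ax, by - ay
    seg_len2 = dx * dx + dy * dy
    t = np.clip(((CE - ax) * dx + (OE - ay) * dy) / seg_len2, 0.0, 1.0)
    cx, cy = ax + t * dx, ay + t * dy
    return float(np.min(np.hypot(CE - cx, OE - cy)))
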