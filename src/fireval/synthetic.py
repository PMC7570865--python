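"""Synthetic fire landscapes with known error structure.

Reference scars are grown as contiguous 4-connected pixel blobs by seeded
random boundary accretion (an Eden-type growth process), which yields the
irregular perimeters and sub-pixel fragmentation that drive mixed-pixel
errors at degraded resolution.  Product maps are derived from a reference
map by injecting controlled omission (missed burned pixels) and commission
(false burned pixels), so downstream confusion-matrix metrics can be checked
against known ground truth.

Fire sizes are drawn log-uniformly within their size class: the field data
this emulates only constrain class counts and class area shares (area totals
dominated by large and very large fires), not a within-class size law, so
the generator keeps every class reachable while allowing heavy-tailed mixes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from shapely import union_all
from shapely.geometry import box

from .errors import EmptyReferenceError, InfeasiblePackingError
from .grid import (
    FIRE_SIZE_CLASSES,
    BurnGrid,
    FireEvent,
    GridSpec,
    categorize_area,
)

__all__ = [
    "LandscapeConfig",
    "PerturbConfig",
    "generate_landscape",
    "perturb_product",
    "generate_multiyear",
]

# 4-connectivity structuring element for erosion/dilation and blob growth.
_CROSS = ndimage.generate_binary_structure(2, 1)

#: Effective size bounds (ha) used when drawing log-uniform sizes: the open
#: lower end of the smallest class starts at one pixel, the open upper end of
#: the largest class is capped at 10x its lower bound.
_MAX_CLASS_FACTOR = 10.0


@dataclass
class LandscapeConfig:
    """Recipe for one synthetic annual fire landscape.

    Parameters
    ----------
    spec
        Grid geometry of the reference map.
    n_fires
        Number of fires per size class, e.g. ``{"small": 3, "large": 1}``.
    seed
        Seed for all randomness (sizes, seeds points, growth order).
    fire_sizes_ha
        Optional explicit fire sizes; overrides class-based drawing.
    annual_total_target_ha
        If set, drawn sizes are rescaled so the total burned area matches
        this target (subject to whole-pixel rounding).
    max_fill
        Safety cap on the fraction of the grid the fires may occupy.
    build_polygons
        Whether to build each fire's perimeter polygon (union of its pixel
        footprints).  Disable for speed in grid-only studies.
    """

    spec: GridSpec
    n_fires: Mapping[str, int] = field(default_factory=dict)
    seed: int = 0
    year: int = 2000
    fire_sizes_ha: Sequence[float] | None = None
    annual_total_target_ha: float | None = None
    max_fill: float = 0.5
    build_polygons: bool = True
    max_retries: int = 50

    def __post_init__(self) -> None:
        known = {name for name, _, _ in FIRE_SIZE_CLASSES}
        for name, count in self.n_fires.items():
            if name not in known:
                raise ValueError(f"unknown fire size class {name!r}")
            if count < 0:
                raise ValueError("fire counts must be >= 0")


@dataclass
class PerturbConfig:
    """Targets for degrading a reference map into a synthetic product map.

    ``target_CE`` is the desired commission error (fraction of the product's
    burned pixels that are not burned in the reference) and ``target_OE`` the
    desired omission error (fraction of reference burned pixels the product
    misses), both realized to the nearest whole pixel.

    ``spatial_mode``:

    * ``"uniform"`` — omitted / committed pixels chosen uniformly at random;
      the statistically clean default for parameter-recovery checks.
    * ``"perimeter_first"`` — omission erodes whole edge layers of each scar
      before thinning the next layer at random, and commission accretes onto
      scar edges; mimics products that miss scar margins.
    """

    target_CE: float = 0.0
    target_OE: float = 0.0
    spatial_mode: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.target_CE < 1:
            raise ValueError("target_CE must lie in [0, 1)")
        if not 0 <= self.target_OE <= 1:
            raise ValueError("target_OE must lie in [0, 1]")
        if self.spatial_mode not in ("uniform", "perimeter_first"):
            raise ValueError(f"unknown spatial_mode {self.spatial_mode!r}")


def _draw_sizes_ha(cfg: LandscapeConfig, rng: np.random.Generator) -> list[float]:
    if cfg.fire_sizes_ha is not None:
        sizes = [float(s) for s in cfg.fire_sizes_ha]
    else:
        sizes = []
        pixel_ha = cfg.spec.pixel_area_ha
        for name, lo, hi in FIRE_SIZE_CLASSES:
            count = cfg.n_fires.get(name, 0)
            lo_eff = max(lo, pixel_ha)
            hi_eff = hi if np.isfinite(hi) else lo * _MAX_CLASS_FACTOR
            if count and hi_eff <= lo_eff:
                raise ValueError(f"class {name!r} unreachable at this pixel size")
            for _ in range(count):
                sizes.append(
                    float(np.exp(rng.uniform(np.log(lo_eff), np.log(hi_eff))))
                )
    if cfg.annual_total_target_ha is not None and sizes:
        sizes = [s * cfg.annual_total_target_ha / sum(sizes) for s in sizes]
    return sizes


def _grow_blob(
    target_px: int,
    occupied: np.ndarray,
    rng: np.random.Generator,
    max_retries: int,
) -> list[tuple[int, int]] | None:
    """Grow one 4-connected blob of ``target_px`` free pixels, or None."""
    n_rows, n_cols = occupied.shape
    free_rows, free_cols = np.nonzero(~occupied)
    if len(free_rows) < target_px:
        return None
    for _ in range(max_retries):
        k = rng.integers(len(free_rows))
        seed = (int(free_rows[k]), int(free_cols[k]))
        blob = {seed}
        frontier: list[tuple[int, int]] = []
        in_frontier: set[tuple[int, int]] = set()

        def push_neighbors(px: tuple[int, int]) -> None:
            r, c = px
            for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if 0 <= nr < n_rows and 0 <= nc < n_cols:
                    cand = (nr, nc)
                    if (
                        not occupied[nr, nc]
                        and cand not in blob
                        and cand not in in_frontier
                    ):
                        frontier.append(cand)
                        in_frontier.add(cand)

        push_neighbors(seed)
        while len(blob) < target_px and frontier:
            idx = rng.integers(len(frontier))
            frontier[idx], frontier[-1] = frontier[-1], frontier[idx]
            px = frontier.pop()
            in_frontier.discard(px)
            if occupied[px] or px in blob:
                continue
            blob.add(px)
            push_neighbors(px)
        if len(blob) == target_px:
            return sorted(blob)
    return None


def _blob_polygon(pixels: Sequence[tuple[int, int]], spec: GridSpec):
    return union_all([spec.pixel_box(r, c) for r, c in pixels])


def generate_landscape(
    config: LandscapeConfig, rng: np.random.Generator | None = None
) -> tuple[list[FireEvent], BurnGrid]:
    """Generate non-overlapping contiguous fire scars and their union map.

    Deterministic for a fixed config and seed.  Raises
    :class:`InfeasiblePackingError` when the requested area cannot be placed
    (grid too small or packing fails after bounded retries).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pixel_ha = config.spec.pixel_area_ha
    sizes_ha = _draw_sizes_ha(config, rng)
    sizes_px = [max(1, round(s / pixel_ha)) for s in sizes_ha]
    total_px = sum(sizes_px)
    capacity = int(config.max_fill * config.spec.n_pixels)
    if total_px > capacity:
        raise InfeasiblePackingError(
            total_px,
            0,
            f"requested {total_px} burned pixels exceed the packing capacity "
            f"{capacity} ({config.max_fill:.0%} of {config.spec.n_pixels} pixels)",
        )

    occupied = np.zeros(config.spec.shape, dtype=bool)
    events: list[FireEvent] = []
    # place big fires first: small ones fit the leftover gaps more easily
    order = sorted(range(len(sizes_px)), key=lambda i: -sizes_px[i])
    placed_px = 0
    for rank, i in enumerate(order):
        blob = _grow_blob(sizes_px[i], occupied, rng, config.max_retries)
        if blob is None:
            raise InfeasiblePackingError(total_px, placed_px)
        for px in blob:
            occupied[px] = True
        placed_px += len(blob)
        area_ha = len(blob) * pixel_ha
        polygon = _blob_polygon(blob, config.spec) if config.build_polygons else None
        events.append(
            FireEvent(
                id=f"fire_{config.year}_{i:03d}",
                year=config.year,
                polygon=polygon,
                area_ha=area_ha,
                category=categorize_area(area_ha),
            )
        )
    events.sort(key=lambda ev: ev.id)
    grid = BurnGrid(config.spec, occupied.astype(np.uint8), year=config.year)
    return events, grid


def _edge_layers(mask: np.ndarray) -> list[np.ndarray]:
    """Peel a binary mask into successive one-pixel edge layers (outermost first)."""
    layers = []
    current = mask.copy()
    while current.any():
        eroded = ndimage.binary_erosion(current, structure=_CROSS)
        layer = current & ~eroded
        layers.append(np.flatnonzero(layer.ravel()))
        current = eroded
    return layers


def perturb_product(
    reference: BurnGrid,
    cfg: PerturbConfig,
    rng: np.random.Generator | None = None,
) -> BurnGrid:
    """Degrade a reference map into a product map with target CE / OE.

    Omission first removes ``round(target_OE * n_ref)`` burned pixels; then
    commission adds unburned pixels until ``added / (kept + added)`` is as
    close to ``target_CE`` as whole pixels allow.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ref_mask = reference.values.astype(bool)
    n_ref = int(ref_mask.sum())
    if n_ref == 0:
        if cfg.target_OE < 1:
            raise EmptyReferenceError(
                "cannot perturb an empty reference with target_OE < 1"
            )
        return BurnGrid(reference.spec, np.zeros_like(reference.values), reference.year)

    n_omit = int(round(cfg.target_OE * n_ref))
    flat = np.flatnonzero(ref_mask.ravel())
    product = ref_mask.copy().ravel()

    if n_omit:
        if cfg.spatial_mode == "uniform":
            drop = rng.choice(flat, size=n_omit, replace=False)
        else:  # perimeter_first: whole edge layers, then random within the next
            drop_parts: list[np.ndarray] = []
            remaining = n_omit
            for layer in _edge_layers(ref_mask):
                if remaining <= 0:
                    break
                if len(layer) <= remaining:
                    drop_parts.append(layer)
                    remaining -= len(layer)
                else:
                    drop_parts.append(rng.choice(layer, size=remaining, replace=False))
                    remaining = 0
            drop = np.concatenate(drop_parts)
        product[drop] = False

    kept = int(product.sum())
    if cfg.target_CE > 0 and kept > 0:
        n_add = int(round(cfg.target_CE * kept / (1.0 - cfg.target_CE)))
        unburned = ~ref_mask.ravel()
        if cfg.spatial_mode == "uniform":
            candidates = np.flatnonzero(unburned)
            if len(candidates) < n_add:
                raise InfeasiblePackingError(
                    n_add, len(candidates), "not enough unburned pixels for target_CE"
                )
            add = rng.choice(candidates, size=n_add, replace=False)
        else:
            # accrete rings of unburned pixels around the reference scar
            # (the scar itself is traversable support, so commission spreads
            # outward from the true perimeter even when edges were omitted)
            add_parts: list[np.ndarray] = []
            support = ref_mask.copy()
            remaining = n_add
            while remaining > 0:
                ring_mask = (
                    ndimage.binary_dilation(support, structure=_CROSS) & ~support
                )
                ring = np.flatnonzero(ring_mask.ravel())
                if len(ring) == 0:
                    raise InfeasiblePackingError(
                        n_add, n_add - remaining,
                        "no adjacent unburned pixels left for target_CE",
                    )
                if len(ring) <= remaining:
                    add_parts.append(ring)
                    remaining -= len(ring)
                else:
                    add_parts.append(rng.choice(ring, size=remaining, replace=False))
                    remaining = 0
                support.ravel()[add_parts[-1]] = True
            add = np.concatenate(add_parts)
        product[add] = True

    return BurnGrid(
        reference.spec,
        product.reshape(ref_mask.shape).astype(np.uint8),
        year=reference.year,
    )


def _year_rng(master_seed: int, year: int) -> np.random.Generator:
    # decouple years: each gets an independent stream keyed by (seed, year)
    return np.random.default_rng(np.random.SeedSequence([master_seed, year]))


def generate_multiyear(
    configs: Mapping[int, tuple[LandscapeConfig, PerturbConfig | None]],
    master_seed: int,
) -> dict[int, tuple[list[FireEvent], BurnGrid, BurnGrid | None]]:
    """Generate per-year (events, reference, product) triples.

    Each year uses an independent random stream derived from
    ``(master_seed, year)``, so adding or removing a year does not change the
    others.  Zero-fire years yield an empty reference and an empty product.
    """
    out: dict[int, tuple[list[FireEvent], BurnGrid, BurnGrid | None]] = {}
    for year, (lcfg, pcfg) in sorted(configs.items()):
        rng = _year_rng(master_seed, year)
        if lcfg.year != year:
            raise ValueError(f"config year {lcfg.year} does not match key {year}")
        events, reference = generate_landscape(lcfg, rng=rng)
        product = None
        if pcfg is not None:
            if reference.burned_pixels == 0:
                product = BurnGrid(
                    reference.spec, np.zeros_like(reference.values), year
                )
            else:
                product = perturb_product(reference, pcfg, rng=rng)
        out[year] = (events, reference, product)
    return out
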