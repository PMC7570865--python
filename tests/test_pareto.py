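"""Pareto boundary construction, AUPB, and the fragmentation regression."""

import numpy as np
import pytest

from fireval import (
    FractionGrid,
    GridSpec,
    LandscapeConfig,
    aggregate_fraction,
    aupb,
    distance_to_boundary,
    fit_te_vs_aupb,
    generate_landscape,
    pareto_boundary,
    threshold_classify,
)
from fireval.errors import DegenerateInputError, EmptyReferenceError
from fireval.pareto import aupb_points


def frac_grid(values) -> FractionGrid:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    spec = GridSpec(0.0, values.shape[0] * 50.0, 50.0, *values.shape)
    return FractionGrid(spec, values, factor=1)


def brute_force_boundary(values):
    """Independent sweep: every distinct positive fraction (plus the empty
    classification) via direct set enumeration, then dominance filtering."""
    v = np.asarray(values, dtype=float).ravel()
    total = v.sum()
    pts = set()
    thresholds = sorted(set(v[v > 0])) + [2.0]  # 2.0 => empty classification
    for p in thresholds:
        burned = v >= p
        nb = burned.sum()
        ce = float((1 - v[burned]).sum() / nb) if nb else 0.0
        oe = float(v[~burned].sum() / total)
        pts.add((round(ce, 12), round(oe, 12)))
    keep = []
    for ce, oe in pts:
        dominated = any(
            (c2 <= ce and o2 <= oe) and (c2 < ce or o2 < oe) for c2, o2 in pts
        )
        if not dominated:
            keep.append((ce, oe))
    return sorted(keep)


class TestThresholdClassify:
    def test_worked_example_at_half(self, toy_fraction):
        assert threshold_classify(toy_fraction, 0.5) == pytest.approx((0.2, 0.2))

    def test_pure_map_is_error_free_at_any_threshold(self):
        fg = frac_grid([[1.0, 0.0], [1.0, 1.0]])
        for p in (0.0, 0.3, 0.7, 1.0):
            assert threshold_classify(fg, p) == (0.0, 0.0)

    def test_unreachable_threshold_gives_empty_detection(self):
        fg = frac_grid([0.2, 0.6, 0.9])
        assert threshold_classify(fg, 1.0) == (0.0, 1.0)

    def test_zero_threshold_excludes_unburned_pixels(self):
        fg = frac_grid([0.5, 0.0, 0.0, 0.0])
        ce, oe = threshold_classify(fg, 0.0)
        assert (ce, oe) == (0.5, 0.0)  # only the mixed pixel is classified

    def test_fully_unburned_grid_rejected(self):
        with pytest.raises(EmptyReferenceError):
            threshold_classify(frac_grid([0.0, 0.0]), 0.5)


class TestParetoBoundary:
    def test_worked_example_three_points(self, toy_fraction):
        curve = pareto_boundary(toy_fraction, 101)
        assert len(curve) == 3
        assert curve.CE == pytest.approx([0.0, 0.2, 1 / 3])
        assert curve.OE == pytest.approx([0.5, 0.2, 0.0])

    def test_pure_map_collapses_to_origin(self):
        curve = pareto_boundary(frac_grid([[1.0, 0.0], [1.0, 1.0]]), 101)
        assert len(curve) == 1
        assert (curve.CE[0], curve.OE[0]) == (0.0, 0.0)
        assert curve.aupb == 0.0

    def test_matches_brute_force_oracle_on_random_grids(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            values = rng.integers(0, 26, size=(8, 8)) / 25.0
            if values.sum() == 0:
                continue
            curve = pareto_boundary(frac_grid(values), "exact")
            got = sorted(zip(curve.CE.round(12), curve.OE.round(12)))
            expected = brute_force_boundary(values)
            assert len(got) == len(expected)
            assert np.allclose(np.array(got), np.array(expected), atol=1e-9)

    def test_oe_strictly_decreasing_in_ce(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            values = rng.random((10, 10)) * (rng.random((10, 10)) < 0.5)
            if values.sum() == 0:
                continue
            curve = pareto_boundary(frac_grid(values), 101)
            assert np.all(np.diff(curve.CE) > 0)
            assert np.all(np.diff(curve.OE) < 0)

    def test_equidistant_matches_exact_when_values_are_coarse(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            values = rng.integers(0, 101, size=(15, 15)) / 100.0
            curve_a = pareto_boundary(frac_grid(values), 1001)
            curve_b = pareto_boundary(frac_grid(values), "exact")
            assert np.array_equal(curve_a.CE, curve_b.CE)
            assert np.array_equal(curve_a.OE, curve_b.OE)
            assert curve_a.aupb == pytest.approx(curve_b.aupb, abs=1e-12)

    def test_padded_pixels_are_excluded(self, random_grid_factory):
        fine = random_grid_factory(5, 30, 31)
        frac = aggregate_fraction(fine, 7, pad=True)
        curve = pareto_boundary(frac, 101)
        assert np.all(curve.CE >= 0) and np.all(curve.CE <= 1)

    def test_bad_steps_rejected(self, toy_fraction):
        with pytest.raises(ValueError):
            pareto_boundary(toy_fraction, 1)
        with pytest.raises(ValueError):
            pareto_boundary(toy_fraction, "approximate")


class TestAupb:
    def test_worked_examples(self, toy_fraction):
        assert pareto_boundary(toy_fraction, 101).aupb == pytest.approx(1 / 12)
        fg = frac_grid([1.0, 1.0, 0.5, 0.0, 0.0])
        assert pareto_boundary(fg, 101).aupb == pytest.approx(1 / 60)

    def test_single_point_has_zero_area(self):
        assert aupb_points([0.3], [0.1]) == 0.0

    def test_in_unit_interval_and_zero_iff_pure(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            values = rng.integers(0, 5, size=(10, 10)) / 4.0
            if values.sum() == 0:
                continue
            a = pareto_boundary(frac_grid(values), 101).aupb
            assert 0.0 <= a <= 1.0
            mixed = np.any((values > 0) & (values < 1))
            assert (a > 0) == bool(mixed)

    def test_coarser_aggregation_does_not_reduce_aupb(self):
        """Degrading resolution creates more mixed pixels, so the area under
        the Pareto boundary grows (or stays) with the aggregation factor."""
        for seed in range(10):
            cfg = LandscapeConfig(
                spec=GridSpec(0, 150 * 50.0, 50.0, 150, 150),
                n_fires={"very_small": 4, "small": 2},
                seed=seed,
                build_polygons=False,
            )
            _, ref = generate_landscape(cfg)
            a5 = pareto_boundary(aggregate_fraction(ref, 5), 101).aupb
            a10 = pareto_boundary(aggregate_fraction(ref, 10), 101).aupb
            assert a10 >= a5


class TestRegression:
    def test_recovers_exact_line(self):
        slope, intercept = 63.1, 0.12
        x = np.array([0.5, 1.1, 2.3, 3.0, 4.4]) / 1000
        pairs = list(zip(x, slope * x + intercept))
        fit = fit_te_vs_aupb(pairs)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(21)
        x = rng.uniform(0, 0.01, 12)
        y = 40 * x + 0.3 + rng.normal(0, 0.05, 12)
        fit = fit_te_vs_aupb(list(zip(x, y)))
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.slope == pytest.approx(beta[0], abs=1e-10)
        assert fit.intercept == pytest.approx(beta[1], abs=1e-10)
        r = np.corrcoef(x, y)[0, 1]
        assert fit.r_squared == pytest.approx(r * r, abs=1e-12)

    def test_too_few_or_degenerate_pairs_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_te_vs_aupb([(0.001, 0.4), (0.002, 0.5)])
        with pytest.raises(DegenerateInputError):
            fit_te_vs_aupb([(0.001, 0.4), (0.001, 0.5), (0.001, 0.6)])


class TestDistance:
    def test_point_on_curve_has_zero_distance(self, toy_fraction):
        curve = pareto_boundary(toy_fraction, 101)
        assert distance_to_boundary(0.2, 0.2, curve) == pytest.approx(0.0)

    def test_distance_to_single_point_curve(self):
        curve = pareto_boundary(frac_grid([[1.0, 0.0], [1.0, 1.0]]), 101)
        assert distance_to_boundary(0.3, 0.4, curve) == pytest.approx(0.5)

    def test_product_errors_lie_above_the_boundary(self, toy_fraction):
        curve = pareto_boundary(toy_fraction, 101)
        assert distance_to_boundary(0.4, 0.5, curve) > 0
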