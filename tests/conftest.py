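import numpy as np
import pytest

from fireval import BurnGrid, FractionGrid, GridSpec


@pytest.fixture
def spec10() -> GridSpec:
    """10x10 grid of 50 m pixels (0.25 ha each), origin at (0, 500)."""
    return GridSpec(0.0, 500.0, 50.0, 10, 10)


@pytest.fixture
def toy_fraction() -> FractionGrid:
    """The 4-pixel mixed map (1.0, 0.6, 0.4, 0.0) used as a worked example."""
    spec = GridSpec(0.0, 100.0, 50.0, 2, 2)
    return FractionGrid(spec, np.array([[1.0, 0.6], [0.4, 0.0]]), factor=1)


def make_burn(spec: GridSpec, values, year: int | None = None) -> BurnGrid:
    return BurnGrid(spec, np.asarray(values, dtype=np.uint8), year=year)


@pytest.fixture
def random_grid_factory():
    """Factory for random binary grids with a per-call seed."""

    def _make(seed: int, n_rows: int = 30, n_cols: int = 30, p: float = 0.3,
              pixel_size: float = 50.0) -> BurnGrid:
        rng = np.random.default_rng(seed)
        spec = GridSpec(0.0, n_rows * pixel_size, pixel_size, n_rows, n_cols)
        values = (rng.random((n_rows, n_cols)) < p).astype(np.uint8)
        return BurnGrid(spec, values)

    return _make
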