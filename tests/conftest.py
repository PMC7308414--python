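import numpy as np
import pytest

from contactddr.genome import BinGrid, ContactMatrix, CoverageTrack


@pytest.fixture
def grid10() -> BinGrid:
    """10 bins of 10 kb on a toy chromosome."""
    return BinGrid("chrT", 0, 100_000, 10_000)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_matrix(grid: BinGrid, rng: np.random.Generator, scale: float = 20.0) -> ContactMatrix:
    """Random symmetric non-negative matrix on ``grid``."""
    n = grid.n_bins
    a = rng.poisson(scale, size=(n, n)).astype(float)
    return ContactMatrix(grid, np.triu(a) + np.triu(a, 1).T)


def random_track(grid: BinGrid, rng: np.random.Generator) -> CoverageTrack:
    return CoverageTrack(grid, rng.poisson(10.0, size=grid.n_bins).astype(float))
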