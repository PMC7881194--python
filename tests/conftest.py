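import numpy as np
import pytest

from ki67grid.grid_io import GridRecord, SlideGridTable
from ki67grid.synthetic import CohortSimParams, SlideSimParams, simulate_cohort


def make_table(counts, case_id="t", grid_size_um=300.0):
    """Build a SlideGridTable from (positive, tumor) pairs."""
    grids = tuple(
        GridRecord(grid_id=f"g{i}", row_index=0, col_index=i, tumor_cells=n, positive_cells=k)
        for i, (k, n) in enumerate(counts)
    )
    return SlideGridTable(case_id=case_id, grid_size_um=grid_size_um, grids=grids)


def random_table(rng, n_grids=None, max_cells=500):
    n_grids = n_grids or rng.integers(1, 30)
    counts = []
    for _ in range(n_grids):
        n = int(rng.integers(1, max_cells))
        k = int(rng.integers(0, n + 1))
        counts.append((k, n))
    return make_table(counts)


@pytest.fixture
def three_grid_table():
    return make_table([(10, 100), (30, 100), (50, 100)])


@pytest.fixture
def six_grid_table():
    # grid LIs 0, 0, 0, 10, 20, 90
    return make_table([(0, 100), (0, 200), (0, 150), (10, 100), (20, 100), (90, 100)])


@pytest.fixture(scope="session")
def cohort_100():
    """100 synthetic cases with slides; shared across IKWG/concordance tests."""
    params = CohortSimParams(n_cases=100, seed=20240901)
    return simulate_cohort(params)


@pytest.fixture(scope="session")
def cohort_50_tables(cohort_100):
    return [table for _, table in cohort_100[:50]]
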