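import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_table, random_table
from ki67grid.errors import EmptySlideError, ValidationError
from ki67grid.grid_io import GridRecord
from ki67grid.ikwg_sim import (
    Level,
    LevelPartition,
    allocate_fields,
    global_average,
    partition_levels,
    run_ikwg_simulation,
    select_fields,
    weighted_average,
)
from ki67grid.scoring import grid_li


def eight_grid_table():
    # grid LIs 0, 0, 5, 10, 15, 20, 25, 30 (all out of 100 cells)
    return make_table([(0, 100), (0, 100), (5, 100), (10, 100), (15, 100), (20, 100), (25, 100), (30, 100)])


class TestPartitionLevels:
    def test_hand_assignment(self):
        p = partition_levels(eight_grid_table())
        assert p.li_min == 0 and p.li_max == 30
        assert p.cutoff_c1 == pytest.approx(10.0)
        assert p.cutoff_c2 == pytest.approx(20.0)
        by = {lvl: sorted(grid_li(g) for g in p.grids_by_level[lvl]) for lvl in Level}
        assert by[Level.ZERO] == [0.0, 0.0]
        assert by[Level.LOW] == [5.0, 10.0]  # upper-inclusive at c1
        assert by[Level.MEDIUM] == [15.0, 20.0]
        assert by[Level.HIGH] == [25.0, 30.0]
        assert all(p.proportions[lvl] == pytest.approx(0.25) for lvl in Level)

    def test_degenerate_range_single_level(self):
        p = partition_levels(make_table([(20, 100)] * 4))
        assert p.range_r == 0.0
        assert p.proportions[Level.HIGH] == 1.0

    def test_all_zero(self):
        p = partition_levels(make_table([(0, 100)] * 3))
        assert p.proportions[Level.ZERO] == 1.0

    def test_empty_slide(self):
        from ki67grid.scoring import apply_qc

        with pytest.raises(EmptySlideError):
            partition_levels(apply_qc(make_table([(0, 10)])))

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = partition_levels(random_table(rng))
            assert sum(p.proportions.values()) == pytest.approx(1.0, abs=1e-12)
            assert len(p.assignment) == sum(len(v) for v in p.grids_by_level.values())


class TestSelectFields:
    def test_one_grid_per_quarter_level(self):
        p = partition_levels(eight_grid_table())
        alloc = allocate_fields(p, n_fields=4)
        assert all(alloc[lvl] == 1 for lvl in Level)

    def test_single_level_gets_all_four(self):
        p = partition_levels(make_table([(20, 100)] * 6))
        ids = select_fields(p, np.random.default_rng(0), n_fields=4)
        assert len(ids) == 4 and len(set(ids)) == 4

    def test_largest_remainder_7_1_1_1(self):
        # proportions (0.7, 0.1, 0.1, 0.1) -> allocation (3, 1, 0, 0)
        counts = [(0, 100)] * 7 + [(5, 100), (15, 100), (25, 100)]
        p = partition_levels(make_table(counts))
        assert p.proportions[Level.ZERO] == pytest.approx(0.7)
        alloc = allocate_fields(p, n_fields=4)
        assert [alloc[lvl] for lvl in Level] == [3, 1, 0, 0]

    def test_capacity_respected(self):
        # fewer grids than fields: take everything available
        p = partition_levels(make_table([(0, 100), (10, 100), (30, 100)]))
        ids = select_fields(p, np.random.default_rng(0), n_fields=4)
        assert sorted(ids) == ["g0", "g1", "g2"]

    def test_one_per_level_strategy(self):
        p = partition_levels(eight_grid_table())
        ids = select_fields(p, np.random.default_rng(0), strategy="one_per_level")
        levels = {p.assignment[i] for i in ids}
        assert len(ids) == 4 and levels == set(Level)

    def test_selection_without_replacement(self):
        p = partition_levels(make_table([(20, 100)] * 10))
        rng = np.random.default_rng(1)
        for _ in range(20):
            ids = select_fields(p, rng, n_fields=4)
            assert len(set(ids)) == len(ids)

    def test_unknown_strategy(self):
        p = partition_levels(eight_grid_table())
        with pytest.raises(ValidationError):
            select_fields(p, np.random.default_rng(0), strategy="bogus")


class TestAverages:
    def test_global_average_pooled(self):
        grids = make_table([(10, 100), (30, 100)]).grids
        assert global_average(grids) == pytest.approx(20.0)

    def test_global_average_single_grid(self):
        g = GridRecord("g", 0, 0, 200, 30)
        assert global_average([g]) == pytest.approx(15.0)

    def test_global_average_empty(self):
        with pytest.raises(ValidationError):
            global_average([])

    def test_weighted_average_hand_example(self):
        # proportions 0.25 each, one grid per level with LIs (0, 5, 15, 25)
        table = eight_grid_table()
        p = partition_levels(table)
        chosen = [table.grids[i] for i in (0, 2, 4, 6)]  # LIs 0, 5, 15, 25
        assert weighted_average(chosen, p) == pytest.approx(11.25)

    def test_weighted_homogeneous_fixed_point(self):
        table = make_table([(30, 100)] * 5)
        p = partition_levels(table)
        assert weighted_average(list(table.grids[:4]), p) == pytest.approx(30.0)

    def test_weighted_all_zero(self):
        table = make_table([(0, 100)] * 4)
        p = partition_levels(table)
        assert weighted_average(list(table.grids[:2]), p) == 0.0

    def test_unsampled_nonzero_level_renormalized(self):
        table = eight_grid_table()
        p = partition_levels(table)
        low = p.grids_by_level[Level.LOW][0]   # LI 5
        high = p.grids_by_level[Level.HIGH][1]  # LI 30
        # sampled: low, high (0.25 each); zero unsampled contributes 0.25 * 0;
        # medium unsampled -> renormalize over 0.75 total mass
        expected = (0.25 * 5 + 0.25 * 30) / 0.75
        assert weighted_average([low, high], p) == pytest.approx(expected)


class TestSimulation:
    def test_homogeneous_slide_zero_width(self):
        table = make_table([(25, 100)] * 8)
        s = run_ikwg_simulation(table, n_replicates=50, seed=0)
        for key in ("global_average", "weighted_average"):
            assert s.medians[key] == pytest.approx(25.0)
            assert s.ci_low[key] == pytest.approx(25.0)
            assert s.ci_high[key] == pytest.approx(25.0)

    def test_seed_determinism_bit_exact(self):
        table = eight_grid_table()
        a = run_ikwg_simulation(table, n_replicates=200, seed=42, keep_replicates=True)
        b = run_ikwg_simulation(table, n_replicates=200, seed=42, keep_replicates=True)
        assert a == b

    def test_different_seeds_differ(self):
        table = eight_grid_table()
        a = run_ikwg_simulation(table, n_replicates=200, seed=1, keep_replicates=True)
        b = run_ikwg_simulation(table, n_replicates=200, seed=2, keep_replicates=True)
        assert a.replicates != b.replicates

    def test_median_matches_exhaustive_enumeration(self):
        """With one pick per level the selection space is a small product set;
        compare the simulated median against the exhaustive mean (the discrete
        distribution here is symmetric, so mean == median)."""
        table = eight_grid_table()
        p = partition_levels(table)
        pools = [p.grids_by_level[lvl] for lvl in Level]
        ws = [
            weighted_average(list(combo), p)
            for combo in itertools.product(*pools)
        ]
        exhaustive_mean = np.mean(ws)
        s = run_ikwg_simulation(table, n_replicates=2000, seed=9)
        assert s.medians["weighted_average"] == pytest.approx(exhaustive_mean, abs=1.0)

    def test_ci_brackets_median(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            table = random_table(rng, n_grids=15)
            s = run_ikwg_simulation(table, n_replicates=200, seed=3)
            for key in ("global_average", "weighted_average"):
                assert s.ci_low[key] <= s.medians[key] <= s.ci_high[key]

    def test_replicate_bounds_property(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            table = random_table(rng, n_grids=12)
            lis = [grid_li(g) for g in table.valid_grids]
            s = run_ikwg_simulation(table, n_replicates=50, seed=7, keep_replicates=True)
            for rep in s.replicates:
                assert min(lis) - 1e-9 <= rep.global_average <= max(lis) + 1e-9
                assert -1e-9 <= rep.weighted_average <= max(lis) + 1e-9

    def test_median_stable_across_seeds(self):
        table = eight_grid_table()
        meds = [
            run_ikwg_simulation(table, n_replicates=1000, seed=s).medians["weighted_average"]
            for s in (1, 2, 3)
        ]
        assert max(meds) - min(meds) < 2.0

    def test_bad_replicate_count(self):
        with pytest.raises(ValidationError):
            run_ikwg_simulation(eight_grid_table(), n_replicates=0, seed=0)
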