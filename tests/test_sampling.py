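"""Spatial partitioning, quota allocation and K-means subset selection."""

from itertools import product

import numpy as np
import pytest

from pixelseg import (
    LabelMap,
    allocate_quotas,
    partition_spatial,
    select_representatives,
)
from pixelseg.neighborhoods import PatchSet
from pixelseg.sampling import SamplingPlan


def make_pool(features, labels=None, regions=None, types=None):
    n = len(features)
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[:, None]
    return PatchSet(
        features=features,
        labels=np.zeros(n, dtype=int) if labels is None else np.asarray(labels),
        scale=0,
        pixel_types=np.zeros(n, dtype=np.int8) if types is None else np.asarray(types),
        image_ids=np.zeros(n, dtype=int),
        coords=np.zeros((n, 2), dtype=int),
        regions=np.zeros(n, dtype=int) if regions is None else np.asarray(regions),
    )


def exhaustive_two_means(points):
    """Best 2-partition by within-cluster squared deviation, by enumeration."""
    n = len(points)
    best, best_cost = None, np.inf
    for mask_bits in range(1, 2 ** (n - 1)):  # fix point 0 in cluster A
        mask = np.array([(mask_bits >> i) & 1 for i in range(n)], dtype=bool)
        cost = 0.0
        for side in (mask, ~mask):
            if side.any():
                c = points[side].mean(axis=0)
                cost += ((points[side] - c) ** 2).sum()
        if cost < best_cost:
            best, best_cost = mask.copy(), cost
    return best


class TestPartitionSpatial:
    def test_single_region(self):
        lm = LabelMap(labels=np.zeros((4, 4), dtype=int))
        np.testing.assert_array_equal(partition_spatial(lm, 1, 0), np.zeros((4, 4)))

    def test_saturated_regions(self):
        lm = LabelMap(labels=np.zeros((2, 3), dtype=int))
        regions = partition_spatial(lm, 6, 0)
        assert sorted(regions.reshape(-1).tolist()) == list(range(6))

    def test_too_many_regions_rejected(self):
        lm = LabelMap(labels=np.zeros((2, 2), dtype=int))
        with pytest.raises(ValueError):
            partition_spatial(lm, 5, 0)

    def test_two_regions_split_2x4_into_halves(self):
        # exhaustive oracle: the optimal coordinate 2-partition of a 2x4
        # grid is left 2x2 vs right 2x2
        lm = LabelMap(labels=np.zeros((2, 4), dtype=int))
        coords = np.array(list(product(range(2), range(4))), dtype=float)
        mask = exhaustive_two_means(coords)
        regions = partition_spatial(lm, 2, seed=0).reshape(-1)
        same = (regions == regions[0])
        assert np.array_equal(same, mask) or np.array_equal(same, ~mask)
        # and the oracle's split is the contiguous half split
        left = coords[:, 1] < 2
        assert np.array_equal(mask, left) or np.array_equal(mask, ~left)

    def test_deterministic_under_seed(self):
        lm = LabelMap(labels=np.zeros((9, 9), dtype=int))
        a = partition_spatial(lm, 3, seed=5)
        b = partition_spatial(lm, 3, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_covers_image_nonoverlapping(self):
        lm = LabelMap(labels=np.zeros((12, 10), dtype=int))
        regions = partition_spatial(lm, 4, seed=1)
        assert regions.shape == (12, 10)
        assert set(np.unique(regions)) == set(range(4))


class TestAllocateQuotas:
    def test_single_cell(self):
        plan = allocate_quotas({(0, 0, 0): 30}, Q=10)
        assert plan.per_cell_quota[(0, 0, 0)] == 10
        plan = allocate_quotas({(0, 0, 0): 5}, Q=10)
        assert plan.per_cell_quota[(0, 0, 0)] == 5

    def test_two_equal_cells_split_evenly(self):
        plan = allocate_quotas({(0, 0, 0): 40, (0, 1, 0): 40}, Q=10)
        assert plan.per_cell_quota == {(0, 0, 0): 5, (0, 1, 0): 5}

    def test_proportional_hand_example(self):
        counts = {(0, 0, 0): 100, (0, 1, 0): 50, (0, 2, 0): 50}
        plan = allocate_quotas(counts, Q=100)
        assert plan.per_cell_quota == {(0, 0, 0): 50, (0, 1, 0): 25, (0, 2, 0): 25}

    def test_quotas_sum_to_min_budget_availability(self, rng):
        for _ in range(20):
            cells = {
                (int(r), int(c), int(t)): int(rng.integers(0, 50))
                for r, c, t in rng.integers(0, 3, size=(5, 3))
            }
            Q = int(rng.integers(1, 120))
            plan = allocate_quotas(cells, Q)
            total = sum(cells.values())
            assert sum(plan.per_cell_quota.values()) == min(Q, total)
            for cell, q in plan.per_cell_quota.items():
                assert 0 <= q <= cells[cell]

    def test_nonpositive_budget_rejected(self):
        with pytest.raises(ValueError):
            allocate_quotas({(0, 0, 0): 5}, Q=0)


class TestSelectRepresentatives:
    def test_quota_equals_pool_returns_everything(self, rng):
        pool = make_pool(rng.uniform(size=(12, 4)))
        plan = SamplingPlan(Q=12, R=1, per_cell_quota={(0, 0, 0): 12})
        sel = select_representatives(pool, plan, seed=0)
        assert len(sel) == 12
        np.testing.assert_array_equal(sel.features, pool.features)

    def test_quota_one_identical_vectors_takes_lowest_index(self):
        pool = make_pool(np.ones((6, 3)))
        pool.coords = np.arange(12).reshape(6, 2)
        plan = SamplingPlan(Q=1, R=1, per_cell_quota={(0, 0, 0): 1})
        sel = select_representatives(pool, plan, seed=0)
        assert len(sel) == 1
        np.testing.assert_array_equal(sel.coords[0], [0, 1])

    def test_two_separated_groups_one_rep_each(self, rng):
        # exhaustive 2-means oracle: optimal split separates the groups
        pts = np.concatenate([rng.normal(0, 0.05, (4, 2)), rng.normal(5, 0.05, (4, 2))])
        mask = exhaustive_two_means(pts)
        assert mask[:4].all() != mask[4:].all()  # oracle splits the two groups
        pool = make_pool(pts)
        plan = SamplingPlan(Q=2, R=1, per_cell_quota={(0, 0, 0): 2})
        sel = select_representatives(pool, plan, seed=0)
        assert len(sel) == 2
        sides = [int((f[0] > 2.5)) for f in sel.features]
        assert sorted(sides) == [0, 1]

    def test_members_of_pool_only(self, rng):
        pool = make_pool(rng.uniform(size=(30, 5)))
        plan = SamplingPlan(Q=7, R=1, per_cell_quota={(0, 0, 0): 7})
        sel = select_representatives(pool, plan, seed=3)
        pool_rows = {tuple(f) for f in pool.features}
        assert all(tuple(f) in pool_rows for f in sel.features)

    def test_determinism(self, rng):
        pool = make_pool(
            rng.uniform(size=(40, 3)),
            labels=rng.integers(0, 2, 40),
            regions=rng.integers(0, 2, 40),
        )
        counts = {}
        for r, c in product(range(2), range(2)):
            n = int(((pool.regions == r) & (pool.labels == c)).sum())
            if n:
                counts[(r, c, 0)] = n
        plan = allocate_quotas(counts, Q=10)
        a = select_representatives(pool, plan, seed=11)
        b = select_representatives(pool, plan, seed=11)
        np.testing.assert_array_equal(a.features, b.features)

    def test_returns_min_q_available_across_random_pools(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 60))
            pool = make_pool(
                rng.uniform(size=(n, 3)),
                labels=rng.integers(0, 3, n),
                regions=rng.integers(0, 2, n),
                types=rng.integers(0, 2, n).astype(np.int8),
            )
            Q = int(rng.integers(1, 80))
            keys = np.stack([pool.regions, pool.labels, pool.pixel_types.astype(np.int64)], axis=1)
            uniq, cnt = np.unique(keys, axis=0, return_counts=True)
            counts = {tuple(int(v) for v in k): int(c) for k, c in zip(uniq, cnt)}
            plan = allocate_quotas(counts, Q)
            sel = select_representatives(pool, plan, seed=2)
            assert len(sel) == min(Q, n)

    def test_class_coverage_with_sufficient_budget(self, rng):
        n = 40
        pool = make_pool(
            rng.uniform(size=(n, 3)),
            labels=np.repeat(np.arange(4), 10),
        )
        keys = np.stack([pool.regions, pool.labels, pool.pixel_types.astype(np.int64)], axis=1)
        uniq, cnt = np.unique(keys, axis=0, return_counts=True)
        counts = {tuple(int(v) for v in k): int(c) for k, c in zip(uniq, cnt)}
        plan = allocate_quotas(counts, Q=8)
        sel = select_representatives(pool, plan, seed=0)
        assert set(sel.labels) == {0, 1, 2, 3}

    def test_empty_cell_quota_redistributed(self, rng):
        pool = make_pool(rng.uniform(size=(10, 2)))
        plan = SamplingPlan(
            Q=6, R=2, per_cell_quota={(0, 0, 0): 3, (1, 0, 0): 3}
        )  # region 1 has no records
        sel = select_representatives(pool, plan, seed=0)
        assert len(sel) == 6
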