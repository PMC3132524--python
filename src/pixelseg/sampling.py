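"""Training-set reduction by two-level K-means.

A pool of P candidate patches is reduced to a budget of Q representatives
per scale.  First the image plane is split into R spatial regions by
K-means on pixel coordinates; then, inside every (region, class, pixel-type)
cell, K-means in feature space with K equal to that cell's quota picks
cluster representatives (the observed patch nearest each centroid), so the
reduced set preserves the spatial, class and boundary/interior mix of the
pool while staying within the compute budget of an SVM fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .io import LabelMap
from .neighborhoods import PatchSet

__all__ = [
    "SamplingPlan",
    "partition_spatial",
    "allocate_quotas",
    "select_representatives",
]

logger = logging.getLogger(__name__)

Cell = tuple[int, int, int]  # (region, class, pixel_type)

# K-means settings (restarts capped for large K, where k-means++ alone is
# already a strong initializer and full restarts dominate the runtime)
_KMEANS_MAX_ITER = 300
_KMEANS_TOL = 1e-4
_FULL_RESTART_MAX_K = 32


@dataclass
class SamplingPlan:
    """Per-cell sample quotas under a total budget Q over R spatial regions."""

    Q: int
    R: int
    per_cell_quota: dict[Cell, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(q < 0 for q in self.per_cell_quota.values()):
            raise ValueError("quotas must be nonnegative")
        if sum(self.per_cell_quota.values()) > self.Q:
            raise ValueError("quotas exceed the budget Q")


def _n_init(k: int) -> int:
    return 10 if k <= _FULL_RESTART_MAX_K else 1


def partition_spatial(lm: LabelMap, R: int, seed: int) -> np.ndarray:
    """Split the image into R regions by K-means on pixel coordinates.

    Returns a region index in {0..R-1} per pixel, same shape as the label
    map.  Deterministic given the seed.
    """
    shape = lm.spatial_shape
    npix = int(np.prod(shape))
    if R < 1:
        raise ValueError("R must be >= 1")
    if R > npix:
        raise ValueError(f"R={R} exceeds pixel count {npix}")
    if R == 1:
        return np.zeros(shape, dtype=np.int64)
    coords = np.stack(
        np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
    ).reshape(npix, -1)
    if R == npix:
        return np.arange(npix, dtype=np.int64).reshape(shape)
    km = KMeans(
        n_clusters=R,
        init="k-means++",
        n_init=10,
        max_iter=_KMEANS_MAX_ITER,
        tol=_KMEANS_TOL,
        random_state=seed % (2**31),
    ).fit(coords.astype(np.float64))
    return km.labels_.astype(np.int64).reshape(shape)


def allocate_quotas(counts: dict[Cell, int], Q: int) -> SamplingPlan:
    """Proportional quota allocation with largest-remainder correction.

    Each cell receives a share of the budget proportional to its available
    count, rounded so quotas sum to min(Q, total available); no quota
    exceeds its cell's availability.
    """
    if Q <= 0:
        raise ValueError("budget Q must be positive")
    cells = sorted(counts)
    avail = np.array([counts[c] for c in cells], dtype=np.int64)
    if (avail < 0).any():
        raise ValueError("negative availability")
    total = int(avail.sum())
    n_nonempty = int((avail > 0).sum())
    if 0 < Q < n_nonempty:
        logger.warning(
            "budget Q=%d is below the number of nonempty cells (%d); "
            "some cells will receive no representatives",
            Q,
            n_nonempty,
        )
    target = min(Q, total)
    regions = sorted({c[0] for c in cells}) if cells else []
    R = len(regions)
    quotas = np.zeros(len(cells), dtype=np.int64)
    if target > 0 and total > 0:
        share = target * avail / total  # exact share; share <= avail
        quotas = np.floor(share).astype(np.int64)
        remainder = share - quotas
        deficit = target - int(quotas.sum())
        # hand out the remaining units by largest fractional part, skipping
        # cells already at capacity; deterministic index tie-break
        order = np.lexsort((np.arange(len(cells)), -remainder))
        i = 0
        while deficit > 0:
            j = order[i % len(cells)]
            if quotas[j] < avail[j]:
                quotas[j] += 1
                deficit -= 1
            i += 1
            if i > 10 * len(cells) * (1 + target):  # safety; unreachable
                raise RuntimeError("quota allocation failed to converge")
    return SamplingPlan(
        Q=Q, R=max(R, 1), per_cell_quota={c: int(q) for c, q in zip(cells, quotas)}
    )


def _cell_representatives(
    feats: np.ndarray, quota: int, seed: int
) -> np.ndarray:
    """Indices (into feats) of quota K-means representatives of one cell."""
    n = len(feats)
    if quota >= n:
        return np.arange(n)
    if quota == 1:
        centroid = feats.mean(axis=0)
        d = np.linalg.norm(feats - centroid, axis=1)
        return np.array([int(np.argmin(d))])  # argmin → lowest index on ties
    km = KMeans(
        n_clusters=quota,
        init="k-means++",
        n_init=_n_init(quota),
        max_iter=_KMEANS_MAX_ITER,
        tol=_KMEANS_TOL,
        random_state=seed % (2**31),
    ).fit(feats)
    reps = []
    for k in range(quota):
        members = np.flatnonzero(km.labels_ == k)
        if members.size == 0:  # empty cluster: K-means kept a stray centroid
            continue
        d = np.linalg.norm(feats[members] - km.cluster_centers_[k], axis=1)
        reps.append(int(members[np.argmin(d)]))
    reps = np.unique(reps)
    if reps.size < quota:  # top up deterministically from unused records
        unused = np.setdiff1d(np.arange(n), reps)
        reps = np.concatenate([reps, unused[: quota - reps.size]])
    return np.sort(reps)


def select_representatives(
    records: PatchSet, plan: SamplingPlan, seed: int
) -> PatchSet:
    """Pick the planned number of representatives from one scale's pool.

    Within each (region, class, pixel-type) cell, K-means with K = quota in
    feature space; the member nearest each centroid is kept.  A positive
    quota on an empty cell is redistributed proportionally among nonempty
    cells of the same class.  Returns min(Q, available) records.
    """
    cells: dict[Cell, np.ndarray] = {}
    keys = np.stack(
        [records.regions, records.labels, records.pixel_types.astype(np.int64)], axis=1
    )
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    for i, key in enumerate(uniq):
        cells[tuple(int(v) for v in key)] = np.flatnonzero(inverse == i)

    quotas = dict(plan.per_cell_quota)
    # redistribute quota assigned to cells absent from this pool
    for cell in list(quotas):
        if quotas[cell] > 0 and cell not in cells:
            orphan = quotas.pop(cell)
            siblings = [c for c in cells if c[1] == cell[1] and quotas.get(c, 0) >= 0]
            if not siblings:
                siblings = sorted(cells)
            if not siblings:
                logger.warning("quota %d for empty cell %s dropped", orphan, cell)
                continue
            logger.info(
                "redistributing quota %d of empty cell %s among %d siblings",
                orphan,
                cell,
                len(siblings),
            )
            sizes = np.array([len(cells[c]) for c in siblings], dtype=float)
            extra = np.floor(orphan * sizes / sizes.sum()).astype(int)
            extra[: orphan - int(extra.sum())] += 1
            for c, e in zip(siblings, extra):
                quotas[c] = quotas.get(c, 0) + int(e)

    chosen: list[np.ndarray] = []
    for j, cell in enumerate(sorted(cells)):
        quota = min(quotas.get(cell, 0), len(cells[cell]))
        if quota <= 0:
            continue
        sub_seed = int(np.random.SeedSequence((seed, j)).generate_state(1)[0] % (2**31))
        idx = cells[cell][_cell_representatives(records.features[cells[cell]], quota, sub_seed)]
        chosen.append(idx)
    if not chosen:
        return records.take(np.array([], dtype=np.int64))
    return records.take(np.sort(np.concatenate(chosen)))
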