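"""Segmentation evaluation metrics.

Semantic (per-pixel) metrics: overall accuracy and the per-class Dice
coefficient 2|A∩B|/(|A|+|B|).  Partition metrics on object maps: the Rand
index (fraction of pixel pairs whose same-segment/different-segment
relation agrees) and the pair-counting Jaccard index, which normalizes
agreements by all pairs except those separated in both partitions and is
therefore unbounded above.  Spatial metrics on binary masks: the Hausdorff
distance (largest distance from any disagreeing pixel to the reference
border) and the normalized sum of distances (NSD), which is 0 for perfect
agreement and 1 for disjoint masks.  Object-level error counting matches
each object to the counterpart sharing the most pixels and tallies
split / merged / added / missing events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "MetricsReport",
    "overall_accuracy",
    "dice",
    "rand_jaccard",
    "hausdorff",
    "nsd",
    "count_errors",
    "evaluate_semantic",
    "evaluate_objects",
]


@dataclass
class MetricsReport:
    """All evaluation numbers for one (prediction, ground truth) pair."""

    overall_accuracy: float | None = None
    dice_per_class: dict[int, float] = field(default_factory=dict)
    rand_index: float | None = None
    jaccard_index: float | None = None
    hausdorff: float | None = None
    nsd: float | None = None
    errors: dict[str, int] = field(default_factory=dict)

    def to_flat_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        if self.overall_accuracy is not None:
            out["overall_accuracy"] = self.overall_accuracy
        for c, d in sorted(self.dice_per_class.items()):
            out[f"dice_class_{c}"] = d
        for name in ("rand_index", "jaccard_index", "hausdorff", "nsd"):
            v = getattr(self, name)
            if v is not None:
                out[name] = v
        for k, v in sorted(self.errors.items()):
            out[f"errors_{k}"] = v
        return out


def _as_arrays(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(getattr(pred, "labels", pred))
    truth = np.asarray(getattr(truth, "labels", truth))
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return pred, truth


def overall_accuracy(pred, truth) -> float:
    """Fraction of pixels whose predicted label equals the ground truth."""
    pred, truth = _as_arrays(pred, truth)
    return float(np.mean(pred == truth))


def dice(pred, truth, c: int) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|) of class c; 1.0 if both sets are empty."""
    pred, truth = _as_arrays(pred, truth)
    a = pred == c
    b = truth == c
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def _pair_counts(pred: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    """(n11, n00, n10, n01) pair counts from the label contingency table.

    n11: pairs co-clustered in both; n00: separated in both; n10: together
    in pred only; n01: together in truth only.
    """
    n = pred.size
    _, pi = np.unique(pred, return_inverse=True)
    _, ti = np.unique(truth, return_inverse=True)
    cont = np.zeros((pi.max() + 1, ti.max() + 1), dtype=np.int64)
    np.add.at(cont, (pi, ti), 1)

    def comb2(x):
        return x * (x - 1) // 2

    total = comb2(n)
    sum_ij = int(comb2(cont).sum())
    sum_i = int(comb2(cont.sum(axis=1)).sum())  # pairs together in pred
    sum_j = int(comb2(cont.sum(axis=0)).sum())  # pairs together in truth
    n11 = sum_ij
    n10 = sum_i - sum_ij
    n01 = sum_j - sum_ij
    n00 = total - sum_i - sum_j + sum_ij
    return n11, n00, n10, n01


def rand_jaccard(pred, truth) -> tuple[float, float]:
    """Rand and pair-counting Jaccard indices of two object partitions.

    RI = (n11 + n00) / all pairs; JI = (n11 + n00) / (n00 + n10 + n01),
    which exceeds 1 when agreeing co-clustered pairs outnumber nothing —
    JI has no upper bound, and higher is better for both.
    """
    pred, truth = _as_arrays(pred, truth)
    if pred.size < 2:
        raise ValueError("Rand index needs at least 2 pixels (one pair)")
    n11, n00, n10, n01 = _pair_counts(pred.reshape(-1), truth.reshape(-1))
    total = n11 + n00 + n10 + n01
    ri = (n11 + n00) / total
    denom = n00 + n10 + n01
    ji = (n11 + n00) / denom if denom > 0 else np.inf
    return float(ri), float(ji)


def _border(mask: np.ndarray) -> np.ndarray:
    """Mask pixels adjacent (by erosion) to the outside."""
    er = ndimage.binary_erosion(mask, border_value=0)
    return mask & ~er


def _border_distance_field(truth_mask: np.ndarray) -> np.ndarray:
    """Euclidean distance from every pixel to the nearest truth-border pixel."""
    border = _border(truth_mask)
    if not border.any():
        raise ValueError("truth mask has an empty border")
    return ndimage.distance_transform_edt(~border)


def hausdorff(pred_mask, truth_mask) -> float:
    """Largest Euclidean distance from a disagreeing pixel to the truth border.

    The disagreement set is the symmetric difference of the two masks; an
    empty symmetric difference gives 0.
    """
    pred_mask, truth_mask = _as_arrays(pred_mask, truth_mask)
    pred_mask = pred_mask.astype(bool)
    truth_mask = truth_mask.astype(bool)
    if not truth_mask.any():
        raise ValueError("empty truth mask")
    disagree = pred_mask ^ truth_mask
    if not disagree.any():
        return 0.0
    dist = _border_distance_field(truth_mask)
    return float(dist[disagree].max())


def nsd(pred_mask, truth_mask) -> float:
    """Normalized sum of border distances over disagreeing pixels.

    Distances to the truth border are summed over the symmetric difference
    and normalized by the same sum over the union of both masks, so
    identical masks score 0 and disjoint masks score 1.
    """
    pred_mask, truth_mask = _as_arrays(pred_mask, truth_mask)
    pred_mask = pred_mask.astype(bool)
    truth_mask = truth_mask.astype(bool)
    if not truth_mask.any():
        raise ValueError("empty truth mask")
    disagree = pred_mask ^ truth_mask
    if not disagree.any():
        return 0.0
    dist = _border_distance_field(truth_mask)
    union = pred_mask | truth_mask
    denom = float(dist[union].sum())
    num = float(dist[disagree].sum())
    if denom == 0.0:
        return 0.0 if num == 0.0 else 1.0
    return min(num / denom, 1.0)


def _plurality_match(objects: np.ndarray, reference: np.ndarray) -> dict[int, int]:
    """Map each positive object id to the reference label sharing most pixels.

    Background (0) is allowed as a match; ties break toward the lowest
    reference label.
    """
    match: dict[int, int] = {}
    for oid in np.unique(objects):
        if oid == 0:
            continue
        ref_labels, counts = np.unique(reference[objects == oid], return_counts=True)
        order = np.lexsort((ref_labels, -counts))
        match[int(oid)] = int(ref_labels[order[0]])
    return match


def count_errors(pred, truth) -> dict[str, int]:
    """Object-level split / merged / added / missing error counts.

    Objects are positive integer labels on background 0.  Each segmented
    object is matched to the reference object (or background) sharing the
    most pixels, and vice versa:

    * split — excess segmented objects mapping to one reference object;
    * merged — excess reference objects mapping to one segmented object;
    * added — segmented objects whose plurality overlap is background;
    * missing — reference objects whose plurality overlap is background.
    """
    pred, truth = _as_arrays(pred, truth)
    if not (np.issubdtype(pred.dtype, np.integer) and np.issubdtype(truth.dtype, np.integer)):
        raise ValueError("object maps must be integer-labeled")
    pred_match = _plurality_match(pred, truth)
    truth_match = _plurality_match(truth, pred)

    added = sum(1 for m in pred_match.values() if m == 0)
    missing = sum(1 for m in truth_match.values() if m == 0)

    split = 0
    hits_per_truth: dict[int, int] = {}
    for m in pred_match.values():
        if m != 0:
            hits_per_truth[m] = hits_per_truth.get(m, 0) + 1
    for k in hits_per_truth.values():
        split += k - 1

    merged = 0
    hits_per_pred: dict[int, int] = {}
    for m in truth_match.values():
        if m != 0:
            hits_per_pred[m] = hits_per_pred.get(m, 0) + 1
    for k in hits_per_pred.values():
        merged += k - 1

    return {"split": split, "merged": merged, "added": added, "missing": missing}


def evaluate_semantic(pred, truth) -> MetricsReport:
    """Accuracy plus per-class Dice for a semantic (class-label) pair."""
    pred_arr, truth_arr = _as_arrays(pred, truth)
    classes = sorted(int(c) for c in np.union1d(np.unique(pred_arr), np.unique(truth_arr)))
    return MetricsReport(
        overall_accuracy=overall_accuracy(pred_arr, truth_arr),
        dice_per_class={c: dice(pred_arr, truth_arr, c) for c in classes},
    )


def evaluate_objects(pred, truth) -> MetricsReport:
    """Full object-map report: accuracy, Dice, RI/JI, Hausdorff, NSD, errors."""
    pred_arr, truth_arr = _as_arrays(pred, truth)
    report = evaluate_semantic(pred_arr > 0, truth_arr > 0)
    report.dice_per_class = {
        int(k): v for k, v in report.dice_per_class.items()
    }
    ri, ji = rand_jaccard(pred_arr, truth_arr)
    report.rand_index = ri
    report.jaccard_index = ji
    report.hausdorff = hausdorff(pred_arr > 0, truth_arr > 0)
    report.nsd = nsd(pred_arr > 0, truth_arr > 0)
    report.errors = count_errors(pred_arr, truth_arr)
    return report
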