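"""Multiscale classifier ensemble: voting strategies and image segmentation.

The S+1 per-scale classifiers are combined per pixel by one of three rules:

* majority voting — each scale casts one vote for its argmax label;
* unweighted confidence voting — posteriors are summed across scales;
* weighted confidence voting (WCV) — posteriors are summed with per-scale
  weights lambda_s chosen to maximize pixel accuracy on training data.

Because the argmax is invariant to positive rescaling of the weights, the
weight search enumerates a grid on the unit simplex; one-hot vectors are in
the grid, so the optimized ensemble can never score below the best single
scale on the data it is fit on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np

from .classifier import ClassifierModel
from .io import Image, LabelMap
from .neighborhoods import PatchSpec, build_pyramid, extract_all_patches

__all__ = [
    "EnsembleModel",
    "majority_vote",
    "confidence_vote",
    "simplex_grid",
    "optimize_weights",
    "segment_image",
]

logger = logging.getLogger(__name__)

STRATEGIES = ("majority", "unweighted_confidence", "weighted_confidence")


@dataclass
class EnsembleModel:
    """S+1 per-scale classifiers plus a voting strategy and weights."""

    models: list[ClassifierModel]
    strategy: str = "weighted_confidence"
    weights: np.ndarray | None = None
    patch_spec: PatchSpec = field(default_factory=PatchSpec)
    train_accuracy: float | None = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not self.models:
            raise ValueError("ensemble requires at least one classifier")
        if self.weights is None:
            self.weights = np.ones(len(self.models))
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if len(self.weights) != len(self.models):
            raise ValueError("one weight per scale required")
        if (self.weights < 0).any() or not (self.weights > 0).any():
            raise ValueError("weights must be nonnegative with at least one positive")

    @property
    def classes(self) -> np.ndarray:
        return self.models[0].classes


def majority_vote(labels_per_scale: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Most-voted class per pixel; ties break toward the smallest class index.

    ``labels_per_scale`` has shape (n_scales, n_pixels).
    """
    labels_per_scale = np.atleast_2d(np.asarray(labels_per_scale))
    classes = np.asarray(classes)
    if classes.size == 0:
        raise ValueError("empty class set")
    votes = np.stack(
        [(labels_per_scale == c).sum(axis=0) for c in classes], axis=0
    )  # (C, npix)
    return classes[np.argmax(votes, axis=0)]  # argmax: first (smallest) on ties


def confidence_vote(
    stack: np.ndarray, weights: np.ndarray, classes: np.ndarray
) -> np.ndarray:
    """Argmax over classes of the weighted sum of per-scale posteriors.

    ``stack`` has shape (n_scales, n_pixels, n_classes); ties break toward
    the smallest class index.
    """
    stack = np.asarray(stack, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if stack.ndim != 3 or len(weights) != stack.shape[0]:
        raise ValueError("stack must be (scales, pixels, classes) matching weights")
    if (weights < 0).any():
        raise ValueError("weights must be nonnegative")
    if not (weights > 0).any():
        raise ValueError("all-zero weight vector")
    scores = np.tensordot(weights, stack, axes=(0, 0))  # (npix, C)
    return np.asarray(classes)[np.argmax(scores, axis=1)]


def simplex_grid(n: int, resolution: float = 0.1) -> np.ndarray:
    """All weight vectors of length n on the unit simplex with the given step.

    With step 1/m these are the compositions of m into n nonnegative parts;
    every one-hot vector is included.
    """
    m = int(round(1.0 / resolution))
    if m < 1:
        raise ValueError("resolution must be <= 1")
    grid = []
    for cuts in combinations_with_replacement(range(m + 1), n - 1):
        parts = np.diff((0,) + cuts + (m,))
        grid.append(parts)
    return np.asarray(grid, dtype=np.float64) / m


def optimize_weights(
    stack_train: np.ndarray,
    truth: np.ndarray,
    classes: np.ndarray,
    resolution: float = 0.1,
) -> tuple[np.ndarray, float]:
    """Exhaustive simplex-grid search for the accuracy-maximizing weights.

    Returns (weights, training accuracy).  Among ties, prefers fewer
    nonzero weights, then the lexicographically first vector; candidates
    are evaluated in chunks to bound memory.
    """
    stack_train = np.asarray(stack_train, dtype=np.float64)
    truth = np.asarray(truth).reshape(-1)
    if truth.size == 0:
        raise ValueError("empty training set")
    if stack_train.ndim != 3 or stack_train.shape[1] != truth.size:
        raise ValueError("stack and truth are misaligned")
    S1 = stack_train.shape[0]
    classes = np.asarray(classes)
    truth_idx = np.searchsorted(classes, truth)
    if not np.array_equal(classes[truth_idx], truth):
        raise ValueError("truth contains labels unknown to the ensemble")

    candidates = simplex_grid(S1, resolution)
    n = truth.size
    flat = stack_train.reshape(S1, -1)  # (S1, n*C)
    accs = np.empty(len(candidates))
    chunk = max(1, int(5e7 / max(flat.shape[1], 1)))
    for start in range(0, len(candidates), chunk):
        W = candidates[start : start + chunk]
        scores = (W @ flat).reshape(len(W), n, classes.size)
        pred = np.argmax(scores, axis=2)
        accs[start : start + chunk] = (pred == truth_idx).mean(axis=1)
    best_acc = accs.max()
    tied = np.flatnonzero(accs >= best_acc - 1e-12)
    nonzeros = (candidates[tied] > 0).sum(axis=1)
    order = sorted(
        range(len(tied)),
        key=lambda i: (nonzeros[i], tuple(-candidates[tied[i]])),
    )
    best = candidates[tied[order[0]]]
    logger.info("optimized weights %s (training accuracy %.4f)", best, best_acc)
    return best, float(best_acc)


def scale_probability_stack(
    img: Image, models: list[ClassifierModel], spec: PatchSpec
) -> np.ndarray:
    """Per-scale posteriors for every pixel: shape (S+1, npix, C)."""
    if not img.is_normalized:
        raise ValueError("image must be normalized with the training-time settings")
    pyr = build_pyramid(img, spec)
    stacks = []
    for model in models:
        feats = extract_all_patches(pyr, model.scale, spec)
        if feats.shape[1] != model.feature_dim:
            raise ValueError(
                f"scale {model.scale}: image yields {feats.shape[1]}-dim patches, "
                f"model expects {model.feature_dim} (channel or dimensionality mismatch)"
            )
        stacks.append(model.predict_proba(feats))
    return np.stack(stacks, axis=0)


def segment_image(
    img: Image, ens: EnsembleModel, spec: PatchSpec | None = None
) -> tuple[LabelMap, np.ndarray]:
    """Label every pixel of a normalized image with the ensemble.

    Test-time pixels use unaugmented patches only.  Returns the predicted
    LabelMap (same spatial shape as the input) and the per-scale
    probability stack of shape (S+1, npix, C).
    """
    spec = spec if spec is not None else ens.patch_spec
    stack = scale_probability_stack(img, ens.models, spec)
    classes = ens.classes
    if ens.strategy == "majority":
        per_scale = np.stack(
            [classes[np.argmax(stack[s], axis=1)] for s in range(stack.shape[0])]
        )
        flat = majority_vote(per_scale, classes)
    else:
        weights = (
            np.ones(stack.shape[0])
            if ens.strategy == "unweighted_confidence"
            else ens.weights
        )
        flat = confidence_vote(stack, weights, classes)
    labels = flat.reshape(img.spatial_shape).astype(np.int64)
    return LabelMap(labels=labels, class_set=[int(c) for c in classes]), stack
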