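"""End-to-end training and segmentation drivers.

``train_ensemble`` runs the full training stage on one or more (image,
label map) pairs: normalization, multiscale patch harvesting with boundary
augmentation, spatial partitioning, two-level K-means subset selection to
the budget Q per scale, per-scale RBF-SVM training with grid search, and —
for the weighted strategy — simplex-grid optimization of the voting
weights on training pixels.  ``save_ensemble`` / ``load_ensemble`` persist
the result as one model file per scale plus a manifest, so segmentation is
reproducible from artifacts alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .classifier import ClassifierModel, train_scale_classifier
from .config import RunConfig
from .ensemble import EnsembleModel, optimize_weights, scale_probability_stack
from .io import Image, LabelMap, normalize_intensity
from .neighborhoods import PatchSet, harvest_patches
from .sampling import allocate_quotas, partition_spatial, select_representatives

__all__ = ["train_ensemble", "save_ensemble", "load_ensemble"]

logger = logging.getLogger(__name__)


def _merge_patchsets(sets: list[PatchSet], scale: int) -> PatchSet:
    return PatchSet(
        features=np.concatenate([p.features for p in sets]),
        labels=np.concatenate([p.labels for p in sets]),
        scale=scale,
        pixel_types=np.concatenate([p.pixel_types for p in sets]),
        image_ids=np.concatenate([p.image_ids for p in sets]),
        coords=np.concatenate([p.coords for p in sets]),
        regions=np.concatenate([p.regions for p in sets]),
    )


def train_ensemble(
    pairs: list[tuple[Image, LabelMap]], config: RunConfig
) -> EnsembleModel:
    """Train the full multiscale ensemble from (image, label map) pairs."""
    if not pairs:
        raise ValueError("need at least one training pair")
    spec = config.patch_spec()
    grid_spec = config.grid_spec()
    first_img = pairs[0][0]
    for i, (img, lm) in enumerate(pairs):
        if img.spatial_shape != lm.spatial_shape:
            raise ValueError(f"training pair {i}: image/label shape mismatch")
        if img.ndim_spatial != first_img.ndim_spatial or img.channels != first_img.channels:
            raise ValueError(f"training pair {i}: dimensionality/channel mismatch")

    # normalize, harvest, annotate spatial regions
    per_scale_sets: dict[int, list[PatchSet]] = {s: [] for s in spec.scales}
    normalized: list[tuple[Image, LabelMap]] = []
    for img_id, (img, lm) in enumerate(pairs):
        if not img.is_normalized:
            img = normalize_intensity(img, config.clip_fraction)
        normalized.append((img, lm))
        regions = partition_spatial(
            lm, config.R, config.sub_seed(f"partition{img_id}")
        ).reshape(-1)
        harvested = harvest_patches(
            img, lm, spec, type_window=config.type_window, image_id=img_id
        )
        npix = int(np.prod(lm.spatial_shape))
        for s, pset in harvested.items():
            # augmented copies inherit the region of their source pixel
            pix_index = np.ravel_multi_index(pset.coords.T, lm.spatial_shape)
            pset.regions = regions[pix_index]
            per_scale_sets[s].append(pset)
            del pix_index
        logger.info("image %d: harvested %d pixels across %d scales", img_id, npix, len(spec.scales))

    # per-scale selection and training
    models: list[ClassifierModel] = []
    for s in spec.scales:
        pool = _merge_patchsets(per_scale_sets[s], s)
        counts: dict[tuple[int, int, int], int] = {}
        keys = np.stack(
            [pool.regions, pool.labels, pool.pixel_types.astype(np.int64)], axis=1
        )
        uniq, cnt = np.unique(keys, axis=0, return_counts=True)
        for key, c in zip(uniq, cnt):
            counts[tuple(int(v) for v in key)] = int(c)
        if config.Q >= len(pool):
            logger.warning(
                "scale %d: budget Q=%d >= pool size %d; using every patch",
                s,
                config.Q,
                len(pool),
            )
            selected = pool
        else:
            plan = allocate_quotas(counts, config.Q)
            selected = select_representatives(
                pool, plan, config.sub_seed(f"select{s}")
            )
        model = train_scale_classifier(
            selected, grid_spec, config.sub_seed(f"train{s}"), scale=s
        )
        logger.info(
            "scale %d: %d training samples, phi=%.4g gamma=%.4g cv_accuracy=%.4f",
            s,
            len(selected),
            model.params.phi,
            model.params.gamma,
            model.cv_accuracy,
        )
        models.append(model)

    ens = EnsembleModel(
        models=models, strategy=config.strategy, patch_spec=spec
    )
    if config.strategy == "weighted_confidence":
        stack, truth = _training_stack(normalized, models, spec, config)
        weights, train_acc = optimize_weights(
            stack, truth, ens.classes, resolution=config.weight_resolution
        )
        ens.weights = weights
        ens.train_accuracy = train_acc
        logger.info("weighted voting: weights=%s train_accuracy=%.4f", weights, train_acc)
    return ens


def _training_stack(
    pairs: list[tuple[Image, LabelMap]],
    models: list[ClassifierModel],
    spec,
    config: RunConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-scale posteriors and truth on (a capped sample of) training pixels."""
    stacks = []
    truths = []
    rng = np.random.default_rng(config.sub_seed("weightpixels"))
    total = sum(int(np.prod(lm.spatial_shape)) for _, lm in pairs)
    cap = config.weight_opt_max_pixels
    for img, lm in pairs:
        npix = int(np.prod(lm.spatial_shape))
        stack = scale_probability_stack(img, models, spec)
        take = npix if total <= cap else max(1, int(round(cap * npix / total)))
        if take < npix:
            idx = np.sort(rng.choice(npix, size=take, replace=False))
            stack = stack[:, idx, :]
            truth = lm.labels.reshape(-1)[idx]
        else:
            truth = lm.labels.reshape(-1)
        stacks.append(stack)
        truths.append(truth)
    return np.concatenate(stacks, axis=1), np.concatenate(truths)


def save_ensemble(ens: EnsembleModel, model_dir: str | Path, config: RunConfig) -> None:
    """Persist one model file per scale plus a JSON manifest."""
    model_dir = Path(model_dir)
    model_dir.mkdir(parents=True, exist_ok=True)
    for model in ens.models:
        model.save(model_dir / f"scale_{model.scale}.joblib")
    manifest = {
        "n_scales": len(ens.models),
        "scales": [m.scale for m in ens.models],
        "classes": [int(c) for c in ens.classes],
        "strategy": ens.strategy,
        "weights": [float(w) for w in ens.weights],
        "train_accuracy": ens.train_accuracy,
        "feature_dim": ens.models[0].feature_dim,
        "patch_spec": {
            "N": ens.patch_spec.N,
            "scales": list(ens.patch_spec.scales),
            "rotation_angles_deg": list(ens.patch_spec.rotation_angles_deg),
            "flips": list(ens.patch_spec.flips),
        },
        "clip_fraction": config.clip_fraction,
        "cv_accuracy_per_scale": [m.cv_accuracy for m in ens.models],
        "params_per_scale": [
            {"phi": m.params.phi, "gamma": m.params.gamma} for m in ens.models
        ],
    }
    (model_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_ensemble(model_dir: str | Path) -> tuple[EnsembleModel, dict]:
    """Load an ensemble persisted by :func:`save_ensemble`."""
    model_dir = Path(model_dir)
    manifest = json.loads((model_dir / "manifest.json").read_text())
    models = [
        ClassifierModel.load(model_dir / f"scale_{s}.joblib")
        for s in manifest["scales"]
    ]
    from .neighborhoods import PatchSpec

    ps = manifest["patch_spec"]
    spec = PatchSpec(
        N=ps["N"],
        scales=tuple(ps["scales"]),
        rotation_angles_deg=tuple(ps["rotation_angles_deg"]),
        flips=tuple(ps["flips"]),
    )
    ens = EnsembleModel(
        models=models,
        strategy=manifest["strategy"],
        weights=np.asarray(manifest["weights"]),
        patch_spec=spec,
        train_accuracy=manifest.get("train_accuracy"),
    )
    return ens, manifest
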