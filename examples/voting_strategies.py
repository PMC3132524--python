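"""Compare majority, unweighted and weighted confidence voting.

Trains a 3-scale ensemble on one textured phantom and segments a held-out
phantom under each voting rule.  Weighted confidence voting searches the
weight simplex for the per-scale weights that maximize training-pixel
accuracy; because every one-hot weighting is a candidate, it can never do
worse than the best single scale on the data it was fit to.
"""

import copy

import numpy as np

from pixelseg import (
    PhantomSpec,
    RunConfig,
    make_texture_phantom,
    normalize_intensity,
    segment_image,
    train_ensemble,
)

config = RunConfig(S=2, Q=1500, R=2, k_folds=5, seed=2, grid_max_fit_samples=512)
img, lm = make_texture_phantom(
    PhantomSpec(kind="texture2d", size=(64, 64), classes=3, seed=31)
)
test_img, test_lm = make_texture_phantom(
    PhantomSpec(kind="texture2d", size=(64, 64), classes=3, seed=32)
)

ensemble = train_ensemble([(normalize_intensity(img), lm)], config)
print("optimized weights:", np.round(ensemble.weights, 2))

nimg = normalize_intensity(test_img)
for strategy in ("majority", "unweighted_confidence", "weighted_confidence"):
    ens = copy.copy(ensemble)
    ens.strategy = strategy
    pred, _ = segment_image(nimg, ens)
    acc = float(np.mean(pred.labels == test_lm.labels))
    print(f"{strategy:>22s}: held-out accuracy {acc:.3f}")
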