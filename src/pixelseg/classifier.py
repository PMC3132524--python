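"""Per-scale multiclass RBF-SVM with two-stage cross-validated grid search.

The soft-margin cost ``phi`` and RBF width ``gamma`` are chosen by k-fold
(default k=10) stratified cross-validation: first a broad log-spaced grid;
whenever the best point sits on a grid boundary that bound is pushed out by
a factor of 5 and the broad search repeats; then a fine local grid around
the broad optimum.  Class posteriors come from pairwise (one-vs-one) Platt
probability coupling, and the predicted label is the argmax of that coupled
posterior, so labels and confidences are mutually consistent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "SVMParams",
    "GridSearchSpec",
    "ClassifierModel",
    "grid_search",
    "train_scale_classifier",
    "predict_proba",
]

logger = logging.getLogger(__name__)

_MAX_BOUND_EXPANSIONS = 6  # per stage, keeps a pathological search finite
_SVC_MAX_ITER = 200_000
_GRID_MAX_ITER = 20_000  # CV fits only rank hyperparameters; cap runaway solves


@dataclass(frozen=True)
class SVMParams:
    """RBF-SVM hyperparameters: soft-margin cost phi and kernel width gamma."""

    phi: float
    gamma: float

    def __post_init__(self) -> None:
        if self.phi <= 0 or self.gamma <= 0:
            raise ValueError("phi and gamma must be positive")


@dataclass(frozen=True)
class GridSearchSpec:
    """Two-stage (phi, gamma) search configuration, all exponents base 2.

    Broad stage: log2-grid from ``*_lo2`` to ``*_hi2`` with step
    ``coarse_step2`` (default x4 per step); a boundary optimum expands that
    bound by ``bound_factor`` (x5).  Fine stage: step ``fine_step2``
    (default sqrt(2)) over +/- ``fine_halfwidth2`` in log2 around the broad
    optimum.
    """

    k: int = 10
    phi_lo2: float = -5.0
    phi_hi2: float = 15.0
    gamma_lo2: float = -15.0
    gamma_hi2: float = 3.0
    coarse_step2: float = 2.0
    fine_step2: float = 0.5
    fine_halfwidth2: float = 2.0
    bound_factor: float = 5.0
    max_fit_samples: int = 1024

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.phi_hi2 < self.phi_lo2 or self.gamma_hi2 < self.gamma_lo2:
            raise ValueError("empty search range")


@dataclass
class ClassifierModel:
    """A trained per-scale classifier with calibrated posteriors."""

    scale: int
    params: SVMParams
    classes: np.ndarray
    estimator: SVC
    cv_accuracy: float
    feature_dim: int

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return predict_proba(self, features)

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Labels as the argmax of the pairwise-coupled posterior."""
        proba = self.predict_proba(features)
        return self.classes[np.argmax(proba, axis=1)]

    def save(self, path: str | Path) -> None:
        joblib.dump(self, Path(path))

    @staticmethod
    def load(path: str | Path) -> "ClassifierModel":
        model = joblib.load(Path(path))
        if not isinstance(model, ClassifierModel):
            raise TypeError(f"{path} does not contain a ClassifierModel")
        return model


def _log2_grid(lo2: float, hi2: float, step2: float) -> np.ndarray:
    n = int(np.floor((hi2 - lo2) / step2 + 1e-9)) + 1
    return lo2 + step2 * np.arange(n)


def _cv_accuracy(
    X: np.ndarray, y: np.ndarray, phi: float, gamma: float, k: int, seed: int
) -> float:
    """Mean stratified k-fold accuracy of an RBF-SVM at (phi, gamma)."""
    k_eff = min(k, int(np.min(np.bincount(y))))
    if k_eff < 2:
        k_eff = 2
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed % (2**31))
    accs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for tr, te in skf.split(X, y):
            clf = SVC(
                kernel="rbf",
                C=phi,
                gamma=gamma,
                cache_size=200,
                max_iter=_GRID_MAX_ITER,
            )
            clf.fit(X[tr], y[tr])
            accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
    return float(np.mean(accs))


def _search_grid(
    X: np.ndarray,
    y: np.ndarray,
    phi_grid: np.ndarray,
    gamma_grid: np.ndarray,
    k: int,
    seed: int,
) -> np.ndarray:
    """CV accuracy at every (phi, gamma) grid point."""
    A = np.empty((len(phi_grid), len(gamma_grid)))
    for i, p2 in enumerate(phi_grid):
        for j, g2 in enumerate(gamma_grid):
            A[i, j] = _cv_accuracy(X, y, 2.0**p2, 2.0**g2, k, seed)
    return A


def _argbest(A: np.ndarray) -> tuple[int, int, np.ndarray]:
    """Tie-broken optimum plus the mask of all CV maxima.

    Ties resolve to the median row (phi) of the tied set, then the median
    tied column (gamma) within that row.  Picking the middle of a tied
    plateau keeps the selection away from degenerate extremes — in the
    strong-regularization (tiny phi) limit the Platt posteriors collapse
    toward uniform even though the decision boundary still separates, and
    in the tiny-gamma limit the kernel flattens out.
    """
    maxima = A >= A.max() - 1e-12
    rows = np.unique(np.nonzero(maxima)[0])
    i = int(rows[(len(rows) - 1) // 2])
    cols = np.nonzero(maxima[i])[0]
    j = int(cols[(len(cols) - 1) // 2])
    return i, j, maxima


def grid_search(
    X: np.ndarray, y: np.ndarray, spec: GridSearchSpec, seed: int
) -> tuple[SVMParams, float]:
    """Two-stage CV grid search for (phi, gamma); returns params and CV accuracy.

    Stage one walks a broad log2 grid and expands any bound the optimum
    lands on by the bound factor before retrying; stage two refines on a
    fine local grid around the broad optimum.  Ties resolve to the middle
    of the tied plateau (see :func:`_argbest`) so that a flat accuracy
    surface cannot drive the parameters to a degenerate extreme.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if len(X) < spec.k:
        raise ValueError(f"need at least k={spec.k} samples, got {len(X)}")
    classes, y_enc = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("grid search requires at least 2 classes")

    rng = np.random.default_rng(seed)
    if len(X) > spec.max_fit_samples:
        sub = _stratified_subsample(y_enc, spec.max_fit_samples, rng)
        Xs, ys = X[sub], y_enc[sub]
    else:
        Xs, ys = X, y_enc

    phi_lo2, phi_hi2 = spec.phi_lo2, spec.phi_hi2
    gamma_lo2, gamma_hi2 = spec.gamma_lo2, spec.gamma_hi2
    log2_bf = np.log2(spec.bound_factor)
    for _ in range(_MAX_BOUND_EXPANSIONS):
        phi_grid = _log2_grid(phi_lo2, phi_hi2, spec.coarse_step2)
        gamma_grid = _log2_grid(gamma_lo2, gamma_hi2, spec.coarse_step2)
        A = _search_grid(Xs, ys, phi_grid, gamma_grid, spec.k, seed)
        i, j, maxima = _argbest(A)
        rows, cols = np.nonzero(maxima)
        expanded = False
        if maxima.all() and maxima.size > 1 and A.max() < 1.0:
            # completely flat, imperfect surface: the range carries no
            # gradient at all, so widen every bound and look again
            phi_lo2 -= log2_bf
            phi_hi2 += log2_bf
            gamma_lo2 -= log2_bf
            gamma_hi2 += log2_bf
            expanded = True
        else:
            # a bound is widened only when every optimum sits on it; a
            # partially tied surface must not push phi toward a degenerate
            # extreme
            if len(phi_grid) > 1 and (rows == 0).all():
                phi_lo2 -= log2_bf
                expanded = True
            elif len(phi_grid) > 1 and (rows == len(phi_grid) - 1).all():
                phi_hi2 += log2_bf
                expanded = True
            if len(gamma_grid) > 1 and (cols == 0).all():
                gamma_lo2 -= log2_bf
                expanded = True
            elif len(gamma_grid) > 1 and (cols == len(gamma_grid) - 1).all():
                gamma_hi2 += log2_bf
                expanded = True
        if not expanded:
            break
    acc = float(A[i, j])
    best_p2, best_g2 = phi_grid[i], gamma_grid[j]

    fine_p = best_p2 + np.arange(-spec.fine_halfwidth2, spec.fine_halfwidth2 + 1e-9, spec.fine_step2)
    fine_g = best_g2 + np.arange(-spec.fine_halfwidth2, spec.fine_halfwidth2 + 1e-9, spec.fine_step2)
    Af = _search_grid(Xs, ys, fine_p, fine_g, spec.k, seed)
    fi, fj, _ = _argbest(Af)
    if Af[fi, fj] > acc:
        best_p2, best_g2, acc = fine_p[fi], fine_g[fj], float(Af[fi, fj])
    params = SVMParams(phi=float(2.0**best_p2), gamma=float(2.0**best_g2))
    logger.info(
        "grid search: phi=2^%.2f gamma=2^%.2f cv_accuracy=%.4f", best_p2, best_g2, acc
    )
    return params, float(acc)


def _stratified_subsample(
    y: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Class-proportional subsample indices, at least one per class."""
    classes = np.unique(y)
    idx: list[np.ndarray] = []
    for c in classes:
        members = np.flatnonzero(y == c)
        take = max(1, int(round(n * len(members) / len(y))))
        take = min(take, len(members))
        idx.append(rng.choice(members, size=take, replace=False))
    return np.sort(np.concatenate(idx))


def train_scale_classifier(
    patches, spec: GridSearchSpec, seed: int, scale: int | None = None
):
    """Fit the multiclass RBF-SVM for one scale's selected training patches.

    Accepts a PatchSet or an ``(X, y)`` pair.  Hyperparameters come from
    :func:`grid_search`; the final model is refit on all samples with
    pairwise Platt probability estimates enabled.
    """
    if isinstance(patches, tuple):
        X, y = patches
        s = 0 if scale is None else scale
    else:
        X, y = patches.features, patches.labels
        s = patches.scale if scale is None else scale
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if len(X) == 0:
        raise ValueError("empty training set")
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2D; mixed dimensions in records")
    if np.unique(y).size < 2:
        raise ValueError("training set contains a single class")

    params, cv_acc = grid_search(X, y, spec, seed)
    est = SVC(
        kernel="rbf",
        C=params.phi,
        gamma=params.gamma,
        probability=True,
        cache_size=500,
        max_iter=_SVC_MAX_ITER,
        random_state=seed % (2**31),
    )
    with warnings.catch_warnings():
        # Platt calibration via the solver's internal CV is the intended
        # mechanism here; silence sklearn's migration advice and any early
        # termination at the (generous) iteration cap.
        warnings.simplefilter("ignore", FutureWarning)
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    return ClassifierModel(
        scale=int(s),
        params=params,
        classes=est.classes_.copy(),
        estimator=est,
        cv_accuracy=cv_acc,
        feature_dim=X.shape[1],
    )


def predict_proba(model: ClassifierModel, features: np.ndarray) -> np.ndarray:
    """Class posterior per sample via pairwise probability coupling.

    Rows are nonnegative and renormalized to sum to one exactly (the
    coupled estimates are normalized to begin with; renormalization guards
    against accumulated floating error).
    """
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if features.shape[1] != model.feature_dim:
        raise ValueError(
            f"feature dimension {features.shape[1]} != model dimension {model.feature_dim}"
        )
    proba = model.estimator.predict_proba(features)
    proba = np.clip(proba, 0.0, None)
    return proba / proba.sum(axis=1, keepdims=True)
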