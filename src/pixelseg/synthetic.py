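"""Labeled synthetic phantoms for end-to-end testing.

Three regimes mirror the structure of common biomedical segmentation
problems without any external data:

* ``texture2d`` — histology-like: the plane is split into irregular
  (Voronoi) regions, each filled with class-specific colored noise, so
  classes differ in mean intensity/color and local texture;
* ``volume3d`` — MRI-like: nested ellipsoid shells in a 3D volume with
  distinct mean intensities, optional smooth multiplicative intensity
  drift to stress robust normalization;
* ``nuclei2d`` — fluorescence-like: bright non-overlapping elliptical
  objects on a dark background, blurred and noised, with per-object labels.

All phantoms are deterministic given the seed, and every label map covers
all requested classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import Image, LabelMap

__all__ = [
    "PhantomSpec",
    "make_texture_phantom",
    "make_volume_phantom",
    "make_nuclei_phantom",
    "make_phantom",
]


@dataclass
class PhantomSpec:
    """Configuration of one synthetic phantom.

    kind : {"texture2d", "volume3d", "nuclei2d"}.
    size : spatial shape (rows, cols) or (slices, rows, cols).
    classes : number of classes C >= 2 (for nuclei2d: object count instead
        via ``n_objects``; the class map is foreground/background).
    noise_sigma : additive Gaussian noise level, on the [0, 1]-ish intensity
        scale of the phantoms.
    channels : 1 for grayscale, 3 for color (texture2d only).
    layout : "voronoi" (irregular boundaries) or "halves" (one straight
        vertical boundary, for exact boundary-count tests; implies 2 regions
        split among classes round-robin).
    base_intensities / texture_sigmas / texture_amps : per-class texture
        parameters; defaults are evenly spaced, mildly textured classes.
    """

    kind: str = "texture2d"
    size: tuple[int, ...] = (128, 128)
    classes: int = 3
    noise_sigma: float = 0.03
    seed: int = 0
    channels: int = 1
    layout: str = "voronoi"
    base_intensities: tuple[float, ...] | None = None
    texture_sigmas: tuple[float, ...] | None = None
    texture_amps: tuple[float, ...] | None = None
    color_means: tuple[tuple[float, ...], ...] | None = None
    # volume3d
    drift_amplitude: float = 0.0
    # nuclei2d
    n_objects: int = 12
    radius_range: tuple[float, float] = (6.0, 12.0)
    background_level: float = 0.1
    foreground_level: float = 0.85
    blur_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("texture2d", "volume3d", "nuclei2d"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.classes < 2:
            raise ValueError("need at least 2 classes")
        if self.layout not in ("voronoi", "halves"):
            raise ValueError(f"unknown layout {self.layout!r}")


def _class_params(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    C = spec.classes
    base = (
        np.asarray(spec.base_intensities)
        if spec.base_intensities is not None
        else np.linspace(0.2, 0.8, C)
    )
    tsig = (
        np.asarray(spec.texture_sigmas)
        if spec.texture_sigmas is not None
        else 1.0 + np.arange(C) % 3
    )
    tamp = (
        np.asarray(spec.texture_amps)
        if spec.texture_amps is not None
        else np.full(C, 0.08)
    )
    if not (len(base) == len(tsig) == len(tamp) == C):
        raise ValueError("per-class parameter lists must have length C")
    return base, tsig, tamp


def _voronoi_labels(size: tuple[int, ...], C: int, rng: np.random.Generator) -> np.ndarray:
    """Partition the plane into C Voronoi cells, one class per cell."""
    npix = int(np.prod(size))
    if C > npix:
        raise ValueError("more classes than pixels")
    for _ in range(100):
        seeds = np.stack([rng.uniform(0, n, size=C) for n in size], axis=1)
        coords = np.stack(
            np.meshgrid(*[np.arange(n) for n in size], indexing="ij"), axis=-1
        ).reshape(npix, len(size))
        d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d2, axis=1).reshape(size)
        if np.unique(labels).size == C:
            return labels
    raise RuntimeError("failed to draw a Voronoi partition covering all classes")


def _halves_labels(size: tuple[int, ...], C: int) -> np.ndarray:
    """C vertical bands of equal width (C=2 gives a single straight boundary)."""
    cols = size[-1]
    band = np.minimum((np.arange(cols) * C) // cols, C - 1)
    return np.broadcast_to(band, size).copy().astype(np.int64)


def _textured_fill(
    labels: np.ndarray,
    spec: PhantomSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fill each class region with its colored noise texture plus noise."""
    C = spec.classes
    base, tsig, tamp = _class_params(spec)
    shape = labels.shape
    img = np.zeros(shape + (spec.channels,), dtype=np.float64)
    for c in range(C):
        mask = labels == c
        if spec.channels > 1 and spec.color_means is not None:
            means = np.asarray(spec.color_means[c], dtype=float)
        else:
            means = np.full(spec.channels, base[c])
        for ch in range(spec.channels):
            if tamp[c] > 0:
                noise = rng.standard_normal(shape)
                tex = ndimage.gaussian_filter(noise, tsig[c])
                std = tex.std()
                tex = tex / std * tamp[c] if std > 0 else tex * 0.0
            else:
                tex = np.zeros(shape)
            img[..., ch][mask] = means[ch] + tex[mask]
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return img


def make_texture_phantom(spec: PhantomSpec) -> tuple[Image, LabelMap]:
    """Histology-like 2D phantom: textured Voronoi regions, one per class."""
    if spec.kind != "texture2d":
        raise ValueError("spec.kind must be 'texture2d'")
    if len(spec.size) != 2:
        raise ValueError("texture2d requires a 2D size")
    rng = np.random.default_rng(spec.seed)
    labels = (
        _voronoi_labels(spec.size, spec.classes, rng)
        if spec.layout == "voronoi"
        else _halves_labels(spec.size, spec.classes)
    )
    img = _textured_fill(labels, spec, rng)
    return Image(data=img, is_normalized=False), LabelMap(labels=labels.astype(np.int64))


def make_volume_phantom(spec: PhantomSpec) -> tuple[Image, LabelMap]:
    """MRI-like 3D phantom: nested ellipsoid shells with distinct means.

    Class 0 is the surround; classes 1..C-1 are concentric shells from the
    outside in.  ``drift_amplitude`` > 0 multiplies intensities by a smooth
    low-frequency field, emulating slowly varying acquisition gain.
    """
    if spec.kind != "volume3d":
        raise ValueError("spec.kind must be 'volume3d'")
    if len(spec.size) != 3:
        raise ValueError("volume3d requires a 3D size")
    C = spec.classes
    size = spec.size
    if min(size) < 2 * C:
        raise ValueError(f"volume {size} too small for {C - 1} nested shells")
    rng = np.random.default_rng(spec.seed)
    center = np.array([(n - 1) / 2 for n in size])
    semi = np.array([n / 2 - 1 for n in size])
    coords = np.stack(
        np.meshgrid(*[np.arange(n) for n in size], indexing="ij"), axis=-1
    ).astype(float)
    r = np.sqrt((((coords - center) / semi) ** 2).sum(axis=-1))  # 1 at the face
    labels = np.zeros(size, dtype=np.int64)
    radii = np.linspace(0.95, 0.25, C - 1)  # outermost shell first
    for c, rad in enumerate(radii, start=1):
        labels[r <= rad] = c
    if np.unique(labels).size != C:
        raise ValueError(f"volume {size} too small: inner shells vanished")
    base, _, _ = _class_params(spec)
    img = base[labels][..., np.newaxis].astype(np.float64)
    if spec.drift_amplitude > 0:
        field = ndimage.gaussian_filter(rng.standard_normal(size), min(size) / 4)
        field = field / max(np.abs(field).max(), 1e-12)
        img = img * (1.0 + spec.drift_amplitude * field)[..., np.newaxis]
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return Image(data=img, is_normalized=False), LabelMap(labels=labels)


def make_nuclei_phantom(spec: PhantomSpec) -> tuple[Image, LabelMap]:
    """Fluorescence-like 2D phantom: bright ellipses on a dark background.

    The label map carries object ids 1..n on background 0; a binary class
    map is ``labels > 0``.  Raises if the requested object count cannot be
    placed without overlap within a bounded number of attempts, reporting
    the count achieved.
    """
    if spec.kind != "nuclei2d":
        raise ValueError("spec.kind must be 'nuclei2d'")
    if len(spec.size) != 2:
        raise ValueError("nuclei2d requires a 2D size")
    rng = np.random.default_rng(spec.seed)
    H, W = spec.size
    labels = np.zeros((H, W), dtype=np.int64)
    yy, xx = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    placed = 0
    attempts = 0
    max_attempts = 200 * spec.n_objects
    margin = 1.5  # minimum clearance between object supports, in pixels
    while placed < spec.n_objects and attempts < max_attempts:
        attempts += 1
        a = rng.uniform(*spec.radius_range)
        b = rng.uniform(*spec.radius_range)
        theta = rng.uniform(0, np.pi)
        cy = rng.uniform(a, H - a)
        cx = rng.uniform(b, W - b)
        ct, st = np.cos(theta), np.sin(theta)
        u = (yy - cy) * ct + (xx - cx) * st
        v = -(yy - cy) * st + (xx - cx) * ct
        ell = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        grown = (u / (a + margin)) ** 2 + (v / (b + margin)) ** 2 <= 1.0
        if not ell.any() or (labels[grown] != 0).any():
            continue
        placed += 1
        labels[ell] = placed
    if placed < spec.n_objects:
        raise RuntimeError(
            f"could only place {placed} of {spec.n_objects} non-overlapping nuclei"
        )
    img = np.where(labels > 0, spec.foreground_level, spec.background_level).astype(
        np.float64
    )
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return Image(data=img[..., np.newaxis], is_normalized=False), LabelMap(labels=labels)


def make_phantom(spec: PhantomSpec) -> tuple[Image, LabelMap]:
    """Dispatch on ``spec.kind``."""
    return {
        "texture2d": make_texture_phantom,
        "volume3d": make_volume_phantom,
        "nuclei2d": make_nuclei_phantom,
    }[spec.kind](spec)
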