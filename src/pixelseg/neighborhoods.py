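"""Multiscale intensity-neighborhood features.

Each pixel is described, at every scale s, by the raw intensities of the
N x N (2D) or N x N x N (3D) window centered on it, flattened into a vector.
Scales keep the window side N fixed but sample the Gaussian-smoothed image
with stride 2**s, so the same small window covers progressively larger
context.  Pixels whose surrounding window touches two or more classes are
"boundary-type"; only those receive rotation/flip augmentation, which models
the local orientation variability of class interfaces without inflating the
far more numerous interior samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import Image, LabelMap

__all__ = [
    "PatchSpec",
    "PatchRecord",
    "PatchSet",
    "ScalePyramid",
    "build_pyramid",
    "extract_patch",
    "extract_all_patches",
    "classify_pixel_type",
    "pixel_type_map",
    "rotation_matrix",
    "augment_patch",
    "harvest_patches",
]

INTERIOR = 0
BOUNDARY = 1


@dataclass(frozen=True)
class PatchSpec:
    """Window/scale/augmentation configuration.

    N : odd window side (default 3).
    scales : iterable of integer scale indices (default 0..4, i.e. 5 scales).
    rotation_angles_deg : signed in-plane (about-Z) rotation angles applied to
        boundary-type windows.
    flips : axis flips in the X-Y plane ("lr", "ud") applied to every rotated
        version including the unrotated one.
    """

    N: int = 3
    scales: tuple[int, ...] = (0, 1, 2, 3, 4)
    rotation_angles_deg: tuple[float, ...] = (45.0, -45.0)
    flips: tuple[str, ...] = ("lr", "ud")

    def __post_init__(self) -> None:
        if self.N < 1 or self.N % 2 == 0:
            raise ValueError("window side N must be odd and positive")
        if len(self.scales) == 0 or min(self.scales) < 0:
            raise ValueError("scales must be nonempty, nonnegative")
        for f in self.flips:
            if f not in ("lr", "ud"):
                raise ValueError(f"unknown flip {f!r}")

    def feature_length(self, ndim_spatial: int, channels: int) -> int:
        return self.N**ndim_spatial * channels


@dataclass
class PatchRecord:
    """One training sample: a flattened neighborhood plus its annotations."""

    features: np.ndarray
    label: int
    scale: int
    pixel_type: int  # INTERIOR or BOUNDARY
    source: tuple[int, tuple[int, ...]]  # (image id, center pixel coordinate)


class PatchSet:
    """Columnar container of PatchRecords at a single scale.

    Stores the feature matrix plus parallel annotation columns, which keeps
    harvesting and K-means selection vectorized; indexing returns a
    :class:`PatchRecord` view for record-level code.
    """

    def __init__(
        self,
        features: np.ndarray,
        labels: np.ndarray,
        scale: int,
        pixel_types: np.ndarray,
        image_ids: np.ndarray,
        coords: np.ndarray,
        regions: np.ndarray | None = None,
    ) -> None:
        self.features = np.asarray(features, dtype=np.float64)
        self.labels = np.asarray(labels, dtype=np.int64)
        self.scale = int(scale)
        self.pixel_types = np.asarray(pixel_types, dtype=np.int8)
        self.image_ids = np.asarray(image_ids, dtype=np.int64)
        self.coords = np.asarray(coords, dtype=np.int64)
        n = len(self.features)
        if not (len(self.labels) == len(self.pixel_types) == len(self.image_ids) == len(self.coords) == n):
            raise ValueError("PatchSet columns must have equal length")
        self.regions = (
            np.zeros(n, dtype=np.int64) if regions is None else np.asarray(regions, dtype=np.int64)
        )

    def __len__(self) -> int:
        return len(self.features)

    def __getitem__(self, i: int) -> PatchRecord:
        return PatchRecord(
            features=self.features[i],
            label=int(self.labels[i]),
            scale=self.scale,
            pixel_type=int(self.pixel_types[i]),
            source=(int(self.image_ids[i]), tuple(self.coords[i])),
        )

    def save(self, path) -> None:
        """Cache the set as a compressed .npz (feature matrix + columns)."""
        np.savez_compressed(
            path,
            features=self.features,
            labels=self.labels,
            scale=np.int64(self.scale),
            pixel_types=self.pixel_types,
            image_ids=self.image_ids,
            coords=self.coords,
            regions=self.regions,
        )

    @classmethod
    def load(cls, path) -> "PatchSet":
        with np.load(path) as data:
            return cls(
                features=data["features"],
                labels=data["labels"],
                scale=int(data["scale"]),
                pixel_types=data["pixel_types"],
                image_ids=data["image_ids"],
                coords=data["coords"],
                regions=data["regions"],
            )

    def take(self, idx: np.ndarray) -> "PatchSet":
        return PatchSet(
            self.features[idx],
            self.labels[idx],
            self.scale,
            self.pixel_types[idx],
            self.image_ids[idx],
            self.coords[idx],
            self.regions[idx],
        )


@dataclass
class ScalePyramid:
    """Gaussian-smoothed copies of one image, one per scale.

    Level 0 is the unsmoothed input; level s uses sigma = 2**(s-1) truncated
    at 4 sigma.  Spatial size is never reduced — subsampling happens at
    patch-extraction time through the stride 2**s.
    """

    levels: dict[int, np.ndarray] = field(default_factory=dict)
    channels: int = 1

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        any_level = next(iter(self.levels.values()))
        return any_level.shape[:-1]


def sigma_for_scale(s: int) -> float:
    return 0.0 if s == 0 else float(2 ** (s - 1))


def build_pyramid(img: Image, spec: PatchSpec) -> ScalePyramid:
    """Smooth the image once per scale (per channel), keeping full size."""
    data = img.data
    nds = img.ndim_spatial
    levels: dict[int, np.ndarray] = {}
    for s in spec.scales:
        sigma = sigma_for_scale(s)
        if sigma == 0.0:
            levels[s] = data.copy()
        else:
            sigmas = (sigma,) * nds + (0.0,)  # never smooth across channels
            levels[s] = ndimage.gaussian_filter(data, sigma=sigmas, truncate=4.0)
    return ScalePyramid(levels=levels, channels=img.channels)


def _window_offsets(N: int, stride: int, ndim: int) -> list[np.ndarray]:
    half = N // 2
    off = (np.arange(N) - half) * stride
    return [off] * ndim


def extract_patch(
    pyr: ScalePyramid, coord: tuple[int, ...], s: int, spec: PatchSpec
) -> np.ndarray:
    """Flattened window at one pixel: stride 2**s on the level-s image.

    Out-of-bounds samples replicate the nearest edge pixel.  Flattening is
    row-major over the window grid with the channel index fastest-varying.
    """
    level = pyr.levels[s]
    shape = level.shape[:-1]
    ndim = len(shape)
    if len(coord) != ndim:
        raise ValueError("coordinate rank does not match image rank")
    if any(c < 0 or c >= n for c, n in zip(coord, shape)):
        raise ValueError(f"coordinate {coord} outside image bounds {shape}")
    stride = 2**s
    axes = _window_offsets(spec.N, stride, ndim)
    idx = np.meshgrid(
        *[np.clip(c + a, 0, n - 1) for c, a, n in zip(coord, axes, shape)],
        indexing="ij",
    )
    return level[tuple(idx)].reshape(-1)


def extract_all_patches(pyr: ScalePyramid, s: int, spec: PatchSpec) -> np.ndarray:
    """Feature matrix for every pixel at scale s, shape (npix, N**dim * C).

    Vectorized equivalent of calling :func:`extract_patch` at each pixel in
    C-order; used for harvesting and whole-image segmentation.
    """
    level = pyr.levels[s]
    shape = level.shape[:-1]
    ndim = len(shape)
    stride = 2**s
    half = spec.N // 2
    offsets = (np.arange(spec.N) - half) * stride
    # gather shifted copies, one per window cell, with edge replication
    shifted = []
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    from itertools import product

    for off in product(offsets, repeat=ndim):
        idx = tuple(
            np.clip(g + o, 0, n - 1) for g, o, n in zip(grids, off, shape)
        )
        shifted.append(level[idx])  # (spatial..., C)
    stacked = np.stack(shifted, axis=-2)  # (spatial..., N**dim, C)
    npix = int(np.prod(shape))
    return stacked.reshape(npix, spec.N**ndim * level.shape[-1])


def classify_pixel_type(
    lm: LabelMap, coord: tuple[int, ...], type_window: int = 3
) -> int:
    """BOUNDARY if the window centered at coord contains >= 2 distinct labels.

    The window is edge-replicated at the image border.
    """
    if type_window % 2 == 0 or type_window < 1:
        raise ValueError("type_window must be odd and positive")
    shape = lm.spatial_shape
    if any(c < 0 or c >= n for c, n in zip(coord, shape)):
        raise ValueError(f"coordinate {coord} outside bounds {shape}")
    half = type_window // 2
    sl = tuple(
        slice(max(0, c - half), min(n, c + half + 1)) for c, n in zip(coord, shape)
    )
    window = lm.labels[sl]
    return BOUNDARY if np.unique(window).size >= 2 else INTERIOR


def pixel_type_map(lm: LabelMap, type_window: int = 3) -> np.ndarray:
    """Boundary/interior type for every pixel at once (edge-replicated)."""
    if type_window % 2 == 0 or type_window < 1:
        raise ValueError("type_window must be odd and positive")
    labels = lm.labels
    maxf = ndimage.maximum_filter(labels, size=type_window, mode="nearest")
    minf = ndimage.minimum_filter(labels, size=type_window, mode="nearest")
    return np.where(maxf != minf, BOUNDARY, INTERIOR).astype(np.int8)


def rotation_matrix(N: int, angle_deg: float) -> np.ndarray:
    """Linear operator on a flattened N x N patch implementing in-plane
    rotation about the window center with bilinear interpolation and
    edge replication.

    Built by rotating each one-hot basis patch with ``scipy.ndimage.rotate``
    (order=1, mode='nearest', reshape=False), so the matrix is exactly that
    interpolation scheme; a patch batch is augmented as ``patches @ M.T``.
    """
    M = np.empty((N * N, N * N))
    for j in range(N * N):
        basis = np.zeros(N * N)
        basis[j] = 1.0
        rot = ndimage.rotate(
            basis.reshape(N, N),
            angle_deg,
            reshape=False,
            order=1,
            mode="nearest",
            prefilter=False,
        )
        M[:, j] = rot.reshape(-1)
    return M


def _flip_permutation(N: int, which: str) -> np.ndarray:
    """Index permutation on one flattened N x N window slice for an X-Y flip."""
    grid = np.arange(N * N).reshape(N, N)
    if which == "lr":  # flip columns
        flipped = np.flip(grid, axis=1)
    elif which == "ud":  # flip rows
        flipped = np.flip(grid, axis=0)
    else:
        raise ValueError(f"unknown flip {which!r}")
    return flipped.reshape(-1)


def _apply_window_op(
    feats: np.ndarray, op: np.ndarray, N: int, ndim: int, channels: int, kind: str
) -> np.ndarray:
    """Apply a per-X-Y-slice operator to a batch of flattened patches.

    ``feats`` has window cells row-major with channels fastest.  For 3D
    windows the operator acts independently on each Z slice (rotations are
    about the Z axis only; flips are in the X-Y plane only).
    """
    n = feats.shape[0]
    ncells = N**ndim
    grid = feats.reshape(n, ncells, channels)
    if ndim == 3:
        grid = grid.reshape(n, N, N * N, channels)
    else:
        grid = grid.reshape(n, 1, N * N, channels)
    if kind == "matrix":
        out = np.einsum("ij,nzjc->nzic", op, grid)
    else:  # permutation
        out = grid[:, :, op, :]
    return out.reshape(n, ncells * channels)


def augment_patch(
    features: np.ndarray, spec: PatchSpec, dim: str, channels: int = 1
) -> list[np.ndarray]:
    """All augmented versions of one patch (original first).

    Rotations (bilinear, about Z) are applied to the window grid, then every
    rotated version — including the unrotated one — is additionally flipped
    left-right and up-down in the X-Y plane.  With the default two angles and
    two flips this yields 3 x 3 = 9 patches.
    """
    ndim = 2 if dim == "2d" else 3
    feats = np.asarray(features, dtype=np.float64)[np.newaxis, :]
    out = _augment_batch(feats, spec, ndim, channels)
    return [out[i, 0] for i in range(out.shape[0])]


def _augment_batch(
    feats: np.ndarray, spec: PatchSpec, ndim: int, channels: int
) -> np.ndarray:
    """(n_versions, n_patches, d) array of augmented copies, original first."""
    N = spec.N
    rotated = [feats]
    for ang in spec.rotation_angles_deg:
        M = rotation_matrix(N, ang)
        rotated.append(_apply_window_op(feats, M, N, ndim, channels, "matrix"))
    versions = list(rotated)
    for which in spec.flips:
        perm = _flip_permutation(N, which)
        for r in rotated:
            versions.append(_apply_window_op(r, perm, N, ndim, channels, "perm"))
    return np.stack(versions, axis=0)


def harvest_patches(
    img: Image,
    lm: LabelMap,
    spec: PatchSpec,
    type_window: int | None = None,
    image_id: int = 0,
    pyramid: ScalePyramid | None = None,
) -> dict[int, PatchSet]:
    """Emit one PatchSet per scale covering every pixel of the image.

    Interior-type pixels contribute their single window; boundary-type pixels
    additionally contribute every rotated/flipped version.  The boundary test
    window defaults to the patch side N.
    """
    if img.spatial_shape != lm.spatial_shape:
        raise ValueError(
            f"image spatial shape {img.spatial_shape} != label map shape {lm.spatial_shape}"
        )
    if type_window is None:
        type_window = spec.N
    ndim = img.ndim_spatial
    channels = img.channels
    pyr = pyramid if pyramid is not None else build_pyramid(img, spec)
    types = pixel_type_map(lm, type_window).reshape(-1)
    labels_flat = lm.labels.reshape(-1)
    coords = np.stack(
        np.meshgrid(*[np.arange(n) for n in img.spatial_shape], indexing="ij"), axis=-1
    ).reshape(-1, ndim)
    boundary_idx = np.flatnonzero(types == BOUNDARY)

    out: dict[int, PatchSet] = {}
    for s in spec.scales:
        feats = extract_all_patches(pyr, s, spec)
        blocks = [feats]
        blk_labels = [labels_flat]
        blk_types = [types]
        blk_coords = [coords]
        if boundary_idx.size:
            aug = _augment_batch(feats[boundary_idx], spec, ndim, channels)[1:]
            for a in aug:
                blocks.append(a)
                blk_labels.append(labels_flat[boundary_idx])
                blk_types.append(types[boundary_idx])
                blk_coords.append(coords[boundary_idx])
        all_feats = np.concatenate(blocks, axis=0)
        all_labels = np.concatenate(blk_labels)
        all_types = np.concatenate(blk_types)
        all_coords = np.concatenate(blk_coords, axis=0)
        out[s] = PatchSet(
            features=all_feats,
            labels=all_labels,
            scale=s,
            pixel_types=all_types,
            image_ids=np.full(len(all_feats), image_id),
            coords=all_coords,
        )
    return out
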