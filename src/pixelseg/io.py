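"""Image / label-map I/O and robust intensity normalization.

Images are held as float arrays with an explicit trailing channel axis:
``(rows, cols, channels)`` for 2D data and ``(slices, rows, cols, channels)``
for 3D volumes.  Label maps are integer arrays over the same spatial grid.

Normalization is percentile-clipped min-max scaling to [0, 1], applied per
channel: outliers beyond a clip fraction (default 1%) at each tail are
discounted before scaling, which makes the mapping robust to hot pixels and
to positive affine changes of the acquisition gain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import tifffile

__all__ = [
    "Image",
    "LabelMap",
    "read_image",
    "read_labelmap",
    "normalize_intensity",
    "write_labelmap",
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return any(name.endswith(s) for s in _NIFTI_SUFFIXES)


@dataclass
class Image:
    """A 2D or 3D intensity image with a trailing channel axis.

    Parameters
    ----------
    data
        Float array of shape ``spatial + (channels,)``; spatial rank 2 or 3.
    is_normalized
        True once intensities have been mapped to [0, 1].
    """

    data: np.ndarray
    is_normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(
                "Image data must have shape spatial + (channels,) with "
                f"spatial rank 2 or 3; got array of rank {self.data.ndim}"
            )
        if self.channels < 1:
            raise ValueError("Image must have at least one channel")

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.data.shape[:-1]

    @property
    def channels(self) -> int:
        return self.data.shape[-1]

    @property
    def ndim_spatial(self) -> int:
        return self.data.ndim - 1


@dataclass
class LabelMap:
    """Integer class (or object) labels on the spatial grid of an Image."""

    labels: np.ndarray
    class_set: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("LabelMap requires an integer-valued array")
        if self.labels.ndim not in (2, 3):
            raise ValueError("LabelMap spatial rank must be 2 or 3")
        present = sorted(int(v) for v in np.unique(self.labels))
        if not self.class_set:
            self.class_set = present
        elif not set(present) <= set(self.class_set):
            raise ValueError("labels contain values outside class_set")

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.labels.shape


def _ensure_channel_axis(arr: np.ndarray, kind: str) -> np.ndarray:
    spatial_rank = 2 if kind == "2d" else 3
    if arr.ndim == spatial_rank:
        return arr[..., np.newaxis]
    if arr.ndim == spatial_rank + 1:
        return arr
    raise ValueError(
        f"array of rank {arr.ndim} is not a {kind} image (with or without channels)"
    )


def read_image(path: str | Path, kind: str = "2d") -> Image:
    """Read a raster image from disk.

    2D: PNG or TIFF (grayscale or RGB).  3D: multi-page TIFF or NIfTI
    (``.nii`` / ``.nii.gz``).  Intensities are returned unmodified as floats;
    ``is_normalized`` is False.
    """
    path = Path(path)
    if kind not in ("2d", "3d"):
        raise ValueError("kind must be '2d' or '3d'")
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if _is_nifti(path):
        if kind != "3d":
            raise ValueError("NIfTI input implies a 3D image")
        arr = np.asanyarray(nib.load(str(path)).dataobj)
    elif path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    else:
        arr = iio.imread(str(path))
    arr = _ensure_channel_axis(np.asarray(arr), kind)
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    return Image(data=arr.astype(np.float64), is_normalized=False)


def read_labelmap(path: str | Path, kind: str = "2d") -> LabelMap:
    """Read an integer label raster written by :func:`write_labelmap`."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if _is_nifti(path):
        arr = np.asanyarray(nib.load(str(path)).dataobj)
    elif path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    else:
        arr = iio.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim == (3 if kind == "3d" else 2) + 1 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    return LabelMap(labels=arr.astype(np.int64))


def normalize_intensity(img: Image, clip_fraction: float = 0.01) -> Image:
    """Map intensities to [0, 1] per channel with percentile clipping.

    For each channel the ``clip_fraction`` and ``1 - clip_fraction``
    quantiles (linear interpolation of the sorted values) define the robust
    range; values are affinely rescaled by it and clamped to [0, 1].  A
    constant channel maps to zeros with a warning rather than failing.
    """
    if not 0 <= clip_fraction < 0.5:
        raise ValueError("clip_fraction must lie in [0, 0.5)")
    data = img.data.astype(np.float64)
    out = np.empty_like(data)
    for c in range(img.channels):
        chan = data[..., c]
        q_lo, q_hi = np.quantile(chan, [clip_fraction, 1.0 - clip_fraction])
        if q_hi == q_lo:
            warnings.warn(
                f"channel {c} has a degenerate intensity range; mapped to zeros",
                stacklevel=2,
            )
            out[..., c] = 0.0
        else:
            out[..., c] = np.clip((chan - q_lo) / (q_hi - q_lo), 0.0, 1.0)
    return Image(data=out, is_normalized=True)


def write_labelmap(lm: LabelMap, path: str | Path) -> None:
    """Write a label map losslessly (PNG/TIFF for 2D, TIFF stack/NIfTI for 3D)."""
    path = Path(path)
    labels = lm.labels
    if labels.min() < 0 or labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels must fit in uint16 (0..65535)")
    arr = labels.astype(np.uint16)
    if str(path) == "" or not path.parent.exists():
        raise IOError(f"cannot write label map to {path!r}")
    if _is_nifti(path):
        if arr.ndim != 3:
            raise ValueError("NIfTI output requires a 3D label map")
        nib.save(nib.Nifti1Image(arr.astype(np.int32), affine=np.eye(4)), str(path))
    elif path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), arr, photometric="minisblack")
    elif path.suffix.lower() == ".png":
        if arr.ndim != 2:
            raise ValueError("PNG output requires a 2D label map")
        iio.imwrite(str(path), arr)
    else:
        raise ValueError(f"unsupported label container: {path.suffix!r}")
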