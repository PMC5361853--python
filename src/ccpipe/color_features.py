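"""Color-space planes, vegetation indices and per-pixel feature tables.

Raw nadir plot images are 3-channel rasters. With the modified camera the
first ("R") channel carries near-infrared signal; all formulas below are
channel-symbolic, so the same code serves ordinary RGB and NIR-substituted
images alike.

Vegetation indices implemented:

========  =============================
name      formula on [0, 1] channels
========  =============================
ExR       1.4*R - G        (excess red)
ExB       1.4*B - G        (excess blue)
ExR_minus_ExB   ExR - ExB
NDI2      (R - B) / (R + B)
NDI3      (R + G - 2B) / (R + G + 2B)
========  =============================

Product indices multiply an NDI plane with a color-space plane to sharpen
the plant/soil contrast: ``NDI2a``, ``NDI3a`` (CIE Lab a-plane, min-max
rescaled per image to [0, 1] before the product) and ``NDI3V`` (HSV value
plane, already in [0, 1]).

The supervised pixel classifiers consume a fixed-order 10-column feature
table per pixel: ``R, G, B, H, S, V, L, a, b, NDI3V``
(:data:`FEATURE_COLUMNS`). The order is part of the trained-model contract.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage import color as _skcolor

__all__ = [
    "FEATURE_COLUMNS",
    "VI_NAMES",
    "PRODUCT_VI_NAMES",
    "ChannelCountError",
    "RGBImage",
    "ColorPlanes",
    "VIImage",
    "load_image",
    "to_color_planes",
    "compute_vi",
    "compute_product_vi",
    "extract_pixel_features",
    "save_vi_tiff",
]

#: Canonical feature-column order for pixel classification (fixed contract).
FEATURE_COLUMNS: tuple[str, ...] = ("R", "G", "B", "H", "S", "V", "L", "a", "b", "NDI3V")

#: Plain vegetation indices accepted by :func:`compute_vi`.
VI_NAMES: tuple[str, ...] = ("ExR", "ExB", "ExR_minus_ExB", "NDI2", "NDI3")

#: Product indices accepted by :func:`compute_product_vi`.
PRODUCT_VI_NAMES: tuple[str, ...] = ("NDI2a", "NDI3a", "NDI3V")


class ChannelCountError(ValueError):
    """Raster does not have exactly 3 channels (and alpha dropping was not requested)."""


@dataclass(frozen=True)
class RGBImage:
    """A 3-channel reflectance image with per-plot metadata.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 3)
        Channel values in [0, 1]. Channel 0 is "R" (possibly a NIR
        substitute), 1 is green, 2 is blue.
    plot_id, date, path
        Optional acquisition metadata carried through the pipeline.
    """

    pixels: np.ndarray
    plot_id: str | None = None
    date: _dt.date | None = None
    path: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ChannelCountError(
                f"expected an (H, W, 3) array, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must contain at least one pixel")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("channel values must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class ColorPlanes:
    """HSV and CIE 1976 L*a*b* planes of one image (sRGB primaries, D65 white)."""

    H: np.ndarray
    S: np.ndarray
    V: np.ndarray
    L: np.ndarray
    a: np.ndarray
    b: np.ndarray


@dataclass(frozen=True)
class VIImage:
    """One named vegetation-index (or product-index) plane."""

    values: np.ndarray
    vi_name: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


_DTYPE_SCALE = {np.dtype("uint8"): 255.0, np.dtype("uint16"): 65535.0}


def load_image(
    path: str | Path,
    *,
    plot_id: str | None = None,
    date: _dt.date | str | None = None,
    drop_alpha: bool = False,
) -> RGBImage:
    """Read a PNG/TIFF/JPEG raster and rescale its channels to [0, 1] floats.

    8-bit inputs are divided by 255, 16-bit by 65535; float inputs must
    already lie in [0, 1]. A 4-channel (RGBA) raster is rejected unless
    ``drop_alpha=True`` is passed explicitly; grayscale is always rejected.

    Raises
    ------
    OSError
        Unreadable, missing or truncated file.
    ChannelCountError
        Wrong number of channels.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except ChannelCountError:  # pragma: no cover - imageio never raises this
        raise
    except Exception as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc

    if raw.ndim == 2:
        raise ChannelCountError(f"{path}: grayscale input; 3 channels required")
    if raw.ndim != 3:
        raise ChannelCountError(f"{path}: unsupported raster shape {raw.shape}")
    if raw.shape[2] == 4:
        if not drop_alpha:
            raise ChannelCountError(
                f"{path}: 4-channel input; pass drop_alpha=True to discard alpha"
            )
        raw = raw[:, :, :3]
    if raw.shape[2] != 3:
        raise ChannelCountError(f"{path}: expected 3 channels, got {raw.shape[2]}")

    scale = _DTYPE_SCALE.get(raw.dtype)
    if scale is not None:
        px = raw.astype(np.float64) / scale
    elif np.issubdtype(raw.dtype, np.floating):
        px = raw.astype(np.float64)
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError(f"{path}: float image values must lie in [0, 1]")
    else:
        raise ValueError(f"{path}: unsupported pixel dtype {raw.dtype}")

    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    return RGBImage(pixels=px, plot_id=plot_id, date=date, path=str(path))


def to_color_planes(img: RGBImage) -> ColorPlanes:
    """Convert an image to HSV and CIE L*a*b* planes.

    HSV follows the standard hexcone model with all planes in [0, 1]
    (``V = max(R, G, B)`` per pixel). Lab uses the sRGB/D65 convention:
    L in [0, 100], a and b signed.
    """
    hsv = _skcolor.rgb2hsv(img.pixels)
    lab = _skcolor.rgb2lab(img.pixels)
    return ColorPlanes(
        H=hsv[:, :, 0],
        S=hsv[:, :, 1],
        V=hsv[:, :, 2],
        L=lab[:, :, 0],
        a=lab[:, :, 1],
        b=lab[:, :, 2],
    )


def compute_vi(img: RGBImage, vi_name: str) -> VIImage:
    """Compute a plain vegetation-index plane.

    Pixels where an NDI denominator is zero (all-black pixels) map to 0,
    the background-neutral value.
    """
    if vi_name not in VI_NAMES:
        raise ValueError(f"unknown vegetation index {vi_name!r}; choose from {VI_NAMES}")
    R = img.pixels[:, :, 0]
    G = img.pixels[:, :, 1]
    B = img.pixels[:, :, 2]
    if vi_name == "ExR":
        values = 1.4 * R - G
    elif vi_name == "ExB":
        values = 1.4 * B - G
    elif vi_name == "ExR_minus_ExB":
        values = (1.4 * R - G) - (1.4 * B - G)
    elif vi_name == "NDI2":
        values = _safe_ratio(R - B, R + B)
    else:  # NDI3
        values = _safe_ratio(R + G - 2.0 * B, R + G + 2.0 * B)
    return VIImage(values=values, vi_name=vi_name)


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=np.float64)
    np.divide(num, den, out=out, where=den != 0.0)
    return out


def compute_product_vi(
    img: RGBImage,
    name: str,
    *,
    planes: ColorPlanes | None = None,
) -> VIImage:
    """Compute a product index: an NDI plane times a color-space plane.

    The signed Lab a-plane is min-max rescaled per image to [0, 1] before
    multiplication so the product keeps the sign structure of the NDI; the
    HSV V-plane is used as-is. A constant a-plane (zero range) rescales to
    all-0.5 with a warning.

    Precomputed ``planes`` may be supplied to avoid repeating the color
    conversion when several products of one image are needed.
    """
    if name not in PRODUCT_VI_NAMES:
        raise ValueError(f"unknown product index {name!r}; choose from {PRODUCT_VI_NAMES}")
    vi = compute_vi(img, "NDI2" if name == "NDI2a" else "NDI3")
    if planes is None:
        planes = to_color_planes(img)
    if name.endswith("a"):
        plane = _rescale_unit(planes.a)
    else:
        plane = planes.V
    return VIImage(values=vi.values * plane, vi_name=name)


def _rescale_unit(plane: np.ndarray) -> np.ndarray:
    lo = float(plane.min())
    hi = float(plane.max())
    if hi == lo:
        warnings.warn(
            "constant a-plane: min-max rescale is degenerate, mapping to 0.5",
            RuntimeWarning,
            stacklevel=3,
        )
        return np.full_like(plane, 0.5, dtype=np.float64)
    return (plane - lo) / (hi - lo)


def extract_pixel_features(
    img: RGBImage,
    sample: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble the per-pixel feature table used by supervised segmentation.

    Parameters
    ----------
    img
        Source image.
    sample : ndarray of int, optional
        Flat (row-major) pixel indices to keep; the full image when omitted.
    labels : ndarray, optional
        Per-pixel class labels ({0 background, 1 plant}); either one value
        per sampled pixel, or an H×W (or flat H*W) array that is subset by
        ``sample``. Adds a ``label`` column.

    Returns
    -------
    DataFrame
        One row per pixel with columns :data:`FEATURE_COLUMNS`
        (``R, G, B, H, S, V, L, a, b, NDI3V``, in that order).
    """
    h, w = img.shape
    n = h * w
    planes = to_color_planes(img)
    ndi3v = compute_product_vi(img, "NDI3V", planes=planes)

    cols = {
        "R": img.pixels[:, :, 0],
        "G": img.pixels[:, :, 1],
        "B": img.pixels[:, :, 2],
        "H": planes.H,
        "S": planes.S,
        "V": planes.V,
        "L": planes.L,
        "a": planes.a,
        "b": planes.b,
        "NDI3V": ndi3v.values,
    }
    mat = np.column_stack([cols[c].ravel() for c in FEATURE_COLUMNS])

    if sample is not None:
        sample = np.asarray(sample, dtype=np.intp).ravel()
        if sample.size and (sample.min() < 0 or sample.max() >= n):
            raise IndexError(f"sample indices out of bounds for {n} pixels")
        mat = mat[sample]

    table = pd.DataFrame(mat, columns=list(FEATURE_COLUMNS))

    if labels is not None:
        lab = np.asarray(labels).ravel()
        if lab.size == n and sample is not None:
            lab = lab[sample]
        if lab.size != len(table):
            raise ValueError(
                f"labels length {lab.size} does not match {len(table)} sampled pixels"
            )
        table["label"] = lab.astype(np.int64)
    return table


def save_vi_tiff(vi: VIImage, path: str | Path) -> None:
    """Write a VI plane as a 32-bit float TIFF for inspection."""
    iio.imwrite(Path(path), vi.values.astype(np.float32), extension=".tiff")
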