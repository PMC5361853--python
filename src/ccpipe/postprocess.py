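"""Mask clean-up and canopy-cover computation.

Raw per-pixel segmentations carry salt-and-pepper noise: isolated
misclassified pixels and small spurious objects (soil clods, specular
spots). Clean-up applies a 5×5 median filter first, then removes connected
components smaller than a minimum object size — strictly smaller, so an
object of exactly the minimum size survives. Canopy cover is then the
plant-pixel fraction of the (optionally ROI-restricted) mask.

The default minimum object size of 400 px matches full-resolution DSLR
plot frames (~21 MP); for smaller rasters scale it with image area.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import remove_small_objects

__all__ = ["CCRecord", "denoise_mask", "canopy_cover"]


@dataclass(frozen=True)
class CCRecord:
    """Canopy cover of one plot on one date, with its pixel counts."""

    plot_id: str | None
    date: _dt.date | str | None
    cc: float
    n_plant_px: int
    n_total_px: int
    illumination_class: int | None = None
    method: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.cc <= 1.0):
            raise ValueError(f"canopy cover must lie in [0, 1], got {self.cc}")


def _as_binary(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mask must be strictly binary (0/1)")
    return arr.astype(np.uint8)


def denoise_mask(
    mask: np.ndarray,
    median_size: int = 5,
    min_object_px: int = 400,
    connectivity: int = 8,
) -> np.ndarray:
    """Remove salt-and-pepper noise from a binary plant mask.

    A ``median_size``×``median_size`` median filter (reflect padding) runs
    first — on a binary image this is a local majority vote that deletes
    isolated pixels and fills pinholes — then connected components with
    fewer than ``min_object_px`` pixels are dropped (8-connectivity by
    default, so diagonal leaf segments stay joined).

    Object removal is subtractive: the result never has more plant pixels
    than the median-filtered mask.
    """
    arr = _as_binary(mask)
    if median_size % 2 == 0 or median_size < 3:
        raise ValueError(f"median_size must be an odd integer >= 3, got {median_size}")
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    if min_object_px < 0:
        raise ValueError("min_object_px must be non-negative")

    med = ndi.median_filter(arr, size=median_size, mode="reflect")
    if min_object_px <= 1:
        return med
    # strictly-smaller convention: objects of exactly min_object_px survive
    # (max_size removes components of size <= value, hence the - 1)
    cleaned = remove_small_objects(
        med.astype(bool),
        max_size=min_object_px - 1,
        connectivity=2 if connectivity == 8 else 1,
    )
    return cleaned.astype(np.uint8)


def canopy_cover(
    mask: np.ndarray,
    roi: tuple[int, int, int, int] | None = None,
    *,
    plot_id: str | None = None,
    date: _dt.date | str | None = None,
    illumination_class: int | None = None,
    method: str | None = None,
) -> CCRecord:
    """Compute canopy cover as the plant-pixel fraction of a mask.

    Parameters
    ----------
    mask : binary ndarray
    roi : (row0, col0, row1, col1), optional
        Half-open rectangle to restrict the computation to; full frame
        when omitted.
    """
    arr = _as_binary(mask)
    if roi is not None:
        r0, c0, r1, c1 = roi
        h, w = arr.shape
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValueError(f"roi {roi} empty or out of bounds for mask shape {arr.shape}")
        arr = arr[r0:r1, c0:c1]
    n_total = int(arr.size)
    n_plant = int(arr.sum())
    return CCRecord(
        plot_id=plot_id,
        date=date,
        cc=n_plant / n_total,
        n_plant_px=n_plant,
        n_total_px=n_total,
        illumination_class=illumination_class,
        method=method,
    )
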