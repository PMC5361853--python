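"""Automated global threshold selection on vegetation-index images.

Two methods are provided:

* **μRow** — exploits the row structure of drilled crops. Averaging a VI
  image across all image rows gives a column profile whose peaks sit on the
  plant rows; a smoothing spline suppresses pixel noise, peaks (and troughs,
  for diagnostics) are detected on the spline, and the threshold is the
  arithmetic mean of the smoothed profile at the detected peaks. The method
  fails honestly — with :class:`NoRowsDetectedError` — on images without a
  row pattern, e.g. bare soil shortly after germination; callers may then
  fall back to Otsu.

* **Otsu** — classic histogram-based between-class-variance maximization,
  implemented over explicit bin edges so the selected threshold is exactly
  reproducible (ties resolve to the lowest candidate).

A mask is produced with the strict convention ``plant = vi > t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.signal import find_peaks

from .color_features import VIImage

__all__ = [
    "NoRowsDetectedError",
    "ThresholdResult",
    "murow_threshold",
    "otsu_threshold",
    "apply_threshold",
]


class NoRowsDetectedError(RuntimeError):
    """No plant-row peaks found in the VI profile (flat or row-less image)."""


@dataclass(frozen=True)
class ThresholdResult:
    """Selected threshold plus μRow diagnostics.

    ``profile`` is the raw column-mean profile (one value per column along
    the chosen axis, each an average over the full image height),
    ``smoothed_profile`` the spline evaluated at the same positions, and
    ``peak_positions`` / ``trough_positions`` index into it. Otsu results
    carry only the threshold.
    """

    threshold: float
    method: str
    axis: str | None = None
    profile: np.ndarray | None = None
    smoothed_profile: np.ndarray | None = None
    peak_positions: np.ndarray | None = None
    trough_positions: np.ndarray | None = None


def _values(vi: VIImage | np.ndarray) -> np.ndarray:
    arr = vi.values if isinstance(vi, VIImage) else np.asarray(vi, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D VI plane, got shape {arr.shape}")
    return arr


# Minimum peak prominence as a fraction of the smoothed profile's value
# range; keeps noise ripples from registering as rows while remaining
# invariant under affine rescaling of the VI.
_PROMINENCE_FRACTION = 0.10


def _murow_one_axis(
    arr: np.ndarray,
    axis: str,
    min_row_spacing_px: int,
    smooth_strength: float,
) -> ThresholdResult | None:
    # "vertical_rows": rows run top-to-bottom, so the profile is indexed by
    # column and each value averages over the image height.
    profile = arr.mean(axis=0) if axis == "vertical_rows" else arr.mean(axis=1)
    n = profile.size
    if n < 2 * min_row_spacing_px:
        raise ValueError(
            f"profile length {n} too short for min_row_spacing_px={min_row_spacing_px}"
        )
    x = np.arange(n, dtype=np.float64)
    lam = float(smooth_strength * n) ** 4
    smoothed = make_smoothing_spline(x, profile, lam=lam)(x)

    vrange = float(smoothed.max() - smoothed.min())
    # a constant profile smooths to numerical ripple; treat it as flat
    if vrange <= 1e-8 * max(float(np.abs(smoothed).max()), 1e-30):
        return None
    prominence = _PROMINENCE_FRACTION * vrange
    peaks, _ = find_peaks(smoothed, distance=min_row_spacing_px, prominence=prominence)
    troughs, _ = find_peaks(-smoothed, distance=min_row_spacing_px, prominence=prominence)
    if peaks.size == 0:
        return None
    return ThresholdResult(
        threshold=float(smoothed[peaks].mean()),
        method="murow",
        axis=axis,
        profile=profile,
        smoothed_profile=smoothed,
        peak_positions=peaks,
        trough_positions=troughs,
    )


def _spacing_cv(peaks: np.ndarray) -> float:
    if peaks.size < 2:
        return np.inf
    gaps = np.diff(peaks).astype(np.float64)
    mean = gaps.mean()
    return float(gaps.std() / mean) if mean > 0 else np.inf


def murow_threshold(
    vi: VIImage | np.ndarray,
    row_axis: str = "auto",
    min_row_spacing_px: int = 12,
    smooth_strength: float = 0.018,
) -> ThresholdResult:
    """Select a global threshold from the peaks of the row-mean VI profile.

    Parameters
    ----------
    vi
        Vegetation-index plane (``NDI3V`` recommended).
    row_axis : {"auto", "vertical_rows", "horizontal_rows"}
        Orientation of the crop rows. ``auto`` evaluates both orientations
        and keeps the one whose inter-peak spacing is most regular (lowest
        coefficient of variation).
    min_row_spacing_px : int
        Minimum pixel distance between neighbouring row peaks.
    smooth_strength : float
        Spline penalty scale; the effective smoothing bandwidth is
        ``smooth_strength`` times the profile length. The default resolves
        typical drilled-row spacing (around 8–12 rows per frame) without
        merging adjacent rows.

    Returns
    -------
    ThresholdResult
        Threshold = mean of the smoothed profile at the detected peaks,
        with full profile/peak/trough diagnostics.

    Raises
    ------
    NoRowsDetectedError
        If no peak passes the spacing/prominence criteria in any allowed
        orientation (e.g. bare soil or pre-emergence imagery).
    """
    arr = _values(vi)
    if row_axis not in ("auto", "vertical_rows", "horizontal_rows"):
        raise ValueError(f"unknown row_axis {row_axis!r}")
    axes = (
        ("vertical_rows", "horizontal_rows") if row_axis == "auto" else (row_axis,)
    )
    candidates: list[ThresholdResult] = []
    for axis in axes:
        res = _murow_one_axis(arr, axis, min_row_spacing_px, smooth_strength)
        if res is not None:
            candidates.append(res)
    if not candidates:
        raise NoRowsDetectedError(
            "no plant-row peaks detected; image may predate row closure "
            "(consider falling back to Otsu)"
        )
    return min(candidates, key=lambda r: _spacing_cv(r.peak_positions))


def otsu_threshold(vi: VIImage | np.ndarray, n_bins: int = 256) -> ThresholdResult:
    """Between-class-variance (Otsu) threshold over an ``n_bins`` histogram.

    The VI values are histogrammed over their [min, max] range; every
    interior bin edge is a candidate threshold and the one maximizing the
    between-class variance (computed on bin centers) is returned. Ties
    resolve to the lowest candidate, making the result deterministic.

    The argmax of the between-class variance is invariant to affine
    transforms of the bin centers, so the criterion is evaluated in exact
    integer arithmetic on bin indices: with integer class weights w0, w1
    and index-weighted sums S0, S1, it is proportional to
    ``(S0*w1 - S1*w0)**2 / (w0*w1)``, compared by cross-multiplication.
    No floating-point round-off can flip the selected bin.
    """
    arr = _values(vi)
    flat = arr.ravel()
    lo, hi = float(flat.min()), float(flat.max())
    if hi == lo:
        raise ValueError("constant VI image: no separable classes for Otsu")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")

    counts, edges = np.histogram(flat, bins=n_bins, range=(lo, hi))
    total = int(counts.sum())
    # integer center surrogate m_k = 2k + 1 (bin centers in half-bin units)
    weighted = counts * (2 * np.arange(n_bins, dtype=np.int64) + 1)
    total_s = int(weighted.sum())

    best_k = -1
    best_num = best_den = 0  # criterion as exact fraction num/den
    w0 = s0 = 0
    for k in range(n_bins - 1):
        w0 += int(counts[k])
        s0 += int(weighted[k])
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        num = (s0 * w1 - (total_s - s0) * w0) ** 2
        den = w0 * w1
        if best_k < 0 or num * best_den > best_num * den:
            best_k, best_num, best_den = k, num, den
    if best_k < 0:
        raise ValueError("degenerate histogram: all mass in one bin")
    return ThresholdResult(threshold=float(edges[best_k + 1]), method="otsu")


def apply_threshold(vi: VIImage | np.ndarray, t: float) -> np.ndarray:
    """Binarize a VI plane: 1 (plant) where ``vi > t``, else 0 (background)."""
    if not np.isfinite(t):
        raise ValueError("threshold must be finite")
    return (_values(vi) > t).astype(np.uint8)
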