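"""Segmentation-accuracy factors against a reference mask.

Given a segmented mask S and a manually delineated reference R, accuracy
over plant pixels (i = 1) is summarized by three factors:

* ``Qseg = |S ∩ R| / |S ∪ R|`` — pixel-wise consistency of the two masks
  (the Jaccard index of the plant sets); 1.0 is a perfect segmentation.
* ``Sr = |S ∩ R| / |R|`` — fraction of true plant pixels recovered
  (recall).
* ``Es = |S ∩ !R| / |R|`` — plant-labelled true-background pixels relative
  to the true plant count; can exceed 1.

All counts are exact integers; division happens last. ``Qseg <= Sr`` holds
for every mask pair since ``|S ∪ R| >= |R|``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["QualityScores", "evaluate_segmentation"]


@dataclass(frozen=True)
class QualityScores:
    """The three accuracy factors plus the plant-pixel counts behind them."""

    qseg: float
    sr: float
    es: float
    n_ref_plant: int
    n_seg_plant: int


def evaluate_segmentation(S: np.ndarray, R: np.ndarray) -> QualityScores:
    """Score a segmented mask ``S`` against a reference mask ``R``.

    Degenerate cases: two empty masks agree vacuously (``qseg = 1``); a
    reference without plant pixels leaves ``sr`` and ``es`` undefined —
    they come back as NaN with a warning, since their denominator ``|R|``
    is zero.
    """
    s = _binary(S, "S")
    r = _binary(R, "R")
    if s.shape != r.shape:
        raise ValueError(f"mask shapes differ: S {s.shape} vs R {r.shape}")

    inter = int(np.logical_and(s, r).sum())
    union = int(np.logical_or(s, r).sum())
    n_ref = int(r.sum())
    n_seg = int(s.sum())
    false_plant = n_seg - inter  # |S ∩ !R|

    qseg = 1.0 if union == 0 else inter / union
    if n_ref == 0:
        warnings.warn(
            "reference mask has no plant pixels: Sr and Es are undefined (NaN)",
            RuntimeWarning,
            stacklevel=2,
        )
        sr = float("nan")
        es = float("nan")
    else:
        sr = inter / n_ref
        es = false_plant / n_ref
    return QualityScores(qseg=qseg, sr=sr, es=es, n_ref_plant=n_ref, n_seg_plant=n_seg)


def _binary(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be strictly binary (0/1)")
    return arr.astype(bool)
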