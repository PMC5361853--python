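"""Illumination-scenario classification from whole-image histograms.

Field light conditions are grouped into two scenarios: low light-contrast
(LLC, class 1), where the full scene detail is captured in the mid-intensity
range, and high light-contrast (HLC, class 2), where images contain
extremely bright (often saturated) and deep-shadow regions. The scenario
label routes each image to the segmentation model trained for it.

The feature is a concatenated 256*3 = 768-vector of the per-channel 8-bit
intensity histograms, normalized to frequencies so images of different
sizes are comparable; the classifier is an RBF-kernel support-vector
machine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.svm import SVC

from .color_features import RGBImage

__all__ = [
    "LLC",
    "HLC",
    "HistFeature",
    "IlluminationModel",
    "NotTrainedError",
    "histogram_features",
    "train_illumination_model",
    "classify_illumination",
]

#: Class label for low light-contrast images.
LLC: int = 1
#: Class label for high light-contrast images.
HLC: int = 2

_N_BINS = 256
_MODEL_FORMAT_VERSION = 1


class NotTrainedError(RuntimeError):
    """Prediction requested from an untrained illumination model."""


@dataclass(frozen=True)
class HistFeature:
    """Concatenated per-channel histogram feature (R block, G block, B block)."""

    vector: np.ndarray
    normalized: bool = True

    def __post_init__(self) -> None:
        vec = np.asarray(self.vector, dtype=np.float64).ravel()
        if vec.size != 3 * _N_BINS:
            raise ValueError(f"feature length must be {3 * _N_BINS}, got {vec.size}")
        object.__setattr__(self, "vector", vec)


def histogram_features(img: RGBImage) -> HistFeature:
    """Compute the 768-long concatenated channel-histogram feature.

    Channel values are quantized to 8-bit levels (0–255), counted in 256
    bins per channel and normalized to frequencies; the three blocks are
    concatenated in R, G, B order.
    """
    levels = np.clip(np.rint(img.pixels * 255.0), 0, 255).astype(np.int64)
    n_px = levels.shape[0] * levels.shape[1]
    blocks = [
        np.bincount(levels[:, :, c].ravel(), minlength=_N_BINS).astype(np.float64) / n_px
        for c in range(3)
    ]
    return HistFeature(vector=np.concatenate(blocks))


@dataclass
class IlluminationModel:
    """Trained SVM over histogram features with its training summary."""

    svc: SVC | None = None
    summary: dict = field(default_factory=dict)

    @property
    def trained(self) -> bool:
        return self.svc is not None

    def save(self, path: str | Path) -> None:
        if not self.trained:
            raise NotTrainedError("refusing to persist an untrained model")
        joblib.dump(
            {"format_version": _MODEL_FORMAT_VERSION, "svc": self.svc, "summary": self.summary},
            Path(path),
        )

    @classmethod
    def load(cls, path: str | Path) -> "IlluminationModel":
        payload = joblib.load(Path(path))
        version = payload.get("format_version")
        if version != _MODEL_FORMAT_VERSION:
            raise ValueError(
                f"illumination model format {version!r} not supported "
                f"(expected {_MODEL_FORMAT_VERSION})"
            )
        return cls(svc=payload["svc"], summary=payload["summary"])


def _as_matrix(features) -> np.ndarray:
    rows = [f.vector if isinstance(f, HistFeature) else np.asarray(f, dtype=np.float64).ravel() for f in features]
    return np.vstack(rows)


def train_illumination_model(
    features,
    labels,
    seed: int = 0,
    *,
    C: float = 1.0,
    gamma: str | float = "scale",
    kernel: str = "rbf",
) -> IlluminationModel:
    """Fit the scenario classifier on labelled histogram features.

    Parameters
    ----------
    features : sequence of HistFeature or 768-vectors
    labels : sequence of int
        Scenario labels in {1 (LLC), 2 (HLC)}; both classes must appear
        at least twice.
    seed : int
        Stored for provenance; the SVC fit itself is deterministic.
    C, gamma, kernel
        SVC hyperparameters; defaults are the standard RBF configuration
        with variance-scaled gamma.
    """
    X = _as_matrix(features)
    y = np.asarray(labels, dtype=np.int64).ravel()
    if X.shape[0] != y.size:
        raise ValueError("features and labels length mismatch")
    classes, counts = np.unique(y, return_counts=True)
    if not np.isin(classes, (LLC, HLC)).all():
        raise ValueError(f"labels must be in {{1 (LLC), 2 (HLC)}}, got {classes}")
    if classes.size < 2 or counts.min() < 2:
        raise ValueError("need at least 2 examples of each illumination class")

    svc = SVC(C=C, gamma=gamma, kernel=kernel, random_state=seed)
    svc.fit(X, y)
    summary = {
        "n_per_class": {int(c): int(n) for c, n in zip(classes, counts)},
        "kernel": kernel,
        "C": C,
        "gamma": gamma,
        "seed": seed,
        "training_accuracy": float(svc.score(X, y)),
    }
    return IlluminationModel(svc=svc, summary=summary)


def classify_illumination(model: IlluminationModel, img: RGBImage) -> int:
    """Predict the scenario label (1 = LLC, 2 = HLC) for one image."""
    if not model.trained:
        raise NotTrainedError("illumination model has not been trained")
    feat = histogram_features(img)
    return int(model.svc.predict(feat.vector[None, :])[0])
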