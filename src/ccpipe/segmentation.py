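"""Pixel-wise plant/background segmentation.

Supervised models — a depth-limited decision tree (DT) or a linear
support-vector machine (SVM) — classify each pixel from the canonical
10-column feature vector (R, G, B, H, S, V, L, a, b, NDI3*V). Models are
trained per illumination scenario: M_LLC on low light-contrast images,
M_HLC on high light-contrast images, and a general M_ALC on the pooled
training set. At run time the illumination classifier's label selects the
scenario model from a :class:`ModelBank` (class 1 -> M_LLC, class 2 ->
M_HLC), with M_ALC as the fallback.

An unsupervised alternative clusters the CIE Lab (a, b) pixel values into
k = 3 groups and takes the cluster with the highest mean NDI3 as plant —
the same construction by which vegetation is picked out of NDVI imagery.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .color_features import FEATURE_COLUMNS, RGBImage, compute_vi, extract_pixel_features, to_color_planes

__all__ = [
    "SCENARIOS",
    "ALGORITHMS",
    "DegenerateClusteringError",
    "SegModel",
    "ModelBank",
    "train_pixel_model",
    "segment_supervised",
    "route_scenario",
    "segment_kmeans",
    "load_training_table",
]

logger = logging.getLogger(__name__)

SCENARIOS: tuple[str, ...] = ("ALC", "HLC", "LLC")
ALGORITHMS: tuple[str, ...] = ("DT", "SVM")

_BANK_FORMAT_VERSION = 1


class DegenerateClusteringError(RuntimeError):
    """Too few distinct (a, b) values to form 3 clusters."""


@dataclass
class SegModel:
    """A trained pixel classifier bound to a scenario and feature order."""

    algorithm: str
    scenario: str
    estimator: object | None = None
    feature_columns: tuple[str, ...] = FEATURE_COLUMNS
    summary: dict = field(default_factory=dict)

    @property
    def trained(self) -> bool:
        return self.estimator is not None


@dataclass
class ModelBank:
    """Per-scenario model collection used for illumination routing."""

    models: dict = field(default_factory=dict)

    def add(self, model: SegModel) -> None:
        self.models[model.scenario] = model

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for scenario, model in self.models.items():
            joblib.dump(
                {"format_version": _BANK_FORMAT_VERSION, "model": model},
                directory / f"M_{scenario}.joblib",
            )

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBank":
        directory = Path(directory)
        bank = cls()
        for path in sorted(directory.glob("M_*.joblib")):
            payload = joblib.load(path)
            if payload.get("format_version") != _BANK_FORMAT_VERSION:
                raise ValueError(f"{path}: unsupported model format")
            bank.add(payload["model"])
        return bank


def _validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"training table lacks canonical feature columns: {missing}")
    if "label" not in table.columns:
        raise ValueError("training table lacks a 'label' column")


def _stratified_subsample(table: pd.DataFrame, max_pixels: int, seed: int) -> pd.DataFrame:
    if len(table) <= max_pixels:
        return table
    rng = np.random.default_rng(seed)
    frac = max_pixels / len(table)
    keep: list[np.ndarray] = []
    for _, grp in table.groupby("label"):
        k = max(1, int(round(frac * len(grp))))
        keep.append(rng.choice(grp.index.to_numpy(), size=min(k, len(grp)), replace=False))
    idx = np.sort(np.concatenate(keep))
    return table.loc[idx]


def train_pixel_model(
    table: pd.DataFrame,
    algorithm: str = "DT",
    scenario: str = "ALC",
    seed: int = 0,
    max_pixels: int = 500_000,
    *,
    max_depth: int = 10,
    C: float = 1.0,
) -> SegModel:
    """Fit a pixel classifier on a labelled feature table.

    Parameters
    ----------
    table : DataFrame
        Must carry the 10 canonical feature columns plus ``label`` in
        {0 background, 1 plant}; both classes must be present.
    algorithm : {"DT", "SVM"}
        Decision tree (depth-limited to ``max_depth``) or linear SVM.
    scenario : {"ALC", "HLC", "LLC"}
        Illumination scenario the training pixels came from.
    max_pixels : int
        Tables larger than this are stratified-subsampled with ``seed``
        before fitting, keeping training tractable on full-frame pixel sets.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"algorithm must be one of {ALGORITHMS}")
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    _validate_table(table)

    table = _stratified_subsample(table, max_pixels, seed)
    X = table[list(FEATURE_COLUMNS)].to_numpy(dtype=np.float64)
    y = table["label"].to_numpy(dtype=np.int64)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training table contains a single class; need plant and background")

    if algorithm == "DT":
        est = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
    else:
        est = LinearSVC(C=C, dual="auto", random_state=seed)
    est.fit(X, y)

    summary = {
        "n_per_class": {int(c): int(n) for c, n in zip(classes, counts)},
        "seed": seed,
        "algorithm": algorithm,
        "scenario": scenario,
        "training_accuracy": float(est.score(X, y)),
    }
    return SegModel(
        algorithm=algorithm,
        scenario=scenario,
        estimator=est,
        feature_columns=FEATURE_COLUMNS,
        summary=summary,
    )


def segment_supervised(model: SegModel, img: RGBImage) -> np.ndarray:
    """Predict a plant mask for every pixel of an image.

    The feature matrix is assembled in the model's recorded column order;
    a mismatch with the canonical order is a hard error, keeping trained
    models portable across runs.
    """
    if not model.trained:
        raise RuntimeError("segmentation model has not been trained")
    feats = extract_pixel_features(img)
    if tuple(model.feature_columns) != tuple(FEATURE_COLUMNS):
        raise ValueError("model feature-column order does not match the canonical order")
    X = feats[list(model.feature_columns)].to_numpy(dtype=np.float64)
    pred = np.asarray(model.estimator.predict(X), dtype=np.uint8)
    return pred.reshape(img.shape)


def route_scenario(bank: ModelBank, cls: int) -> SegModel:
    """Pick the scenario model for an illumination label (1 LLC, 2 HLC).

    Falls back to the general M_ALC model, with a logged warning, when the
    scenario-specific model is absent.
    """
    if not bank.models:
        raise ValueError("empty model bank: no segmentation model available")
    if cls not in (1, 2):
        raise ValueError(f"illumination class must be 1 (LLC) or 2 (HLC), got {cls}")
    scenario = "LLC" if cls == 1 else "HLC"
    if scenario in bank.models:
        return bank.models[scenario]
    if "ALC" in bank.models:
        logger.warning("no %s model in bank; falling back to the general ALC model", scenario)
        return bank.models["ALC"]
    raise ValueError(f"model bank holds neither {scenario} nor ALC")


def segment_kmeans(
    img: RGBImage,
    seed: int = 0,
    *,
    n_clusters: int = 3,
    n_init: int = 10,
) -> np.ndarray:
    """Unsupervised plant mask via K-means on the Lab (a, b) plane.

    Pixels are clustered into ``n_clusters`` (3) groups by their (a, b)
    chromaticity; the cluster with the highest mean NDI3 is taken as plant,
    with ties broken toward the larger cluster.
    """
    planes = to_color_planes(img)
    ab = np.column_stack([planes.a.ravel(), planes.b.ravel()])
    if np.unique(ab, axis=0).shape[0] < n_clusters:
        raise DegenerateClusteringError(
            f"fewer than {n_clusters} distinct (a, b) values; cannot cluster"
        )
    km = KMeans(n_clusters=n_clusters, n_init=n_init, random_state=seed)
    labels = km.fit_predict(ab)

    ndi3 = compute_vi(img, "NDI3").values.ravel()
    means = np.array([ndi3[labels == k].mean() for k in range(n_clusters)])
    sizes = np.array([(labels == k).sum() for k in range(n_clusters)])
    # lexicographic argmax: highest mean NDI3, ties toward the larger cluster
    order = np.lexsort((sizes, means))
    plant_cluster = int(order[-1])
    return (labels == plant_cluster).astype(np.uint8).reshape(img.shape)


def load_training_table(path: str | Path) -> pd.DataFrame:
    """Read an externally labelled pixel table (CSV: 10 features + label)."""
    table = pd.read_csv(path)
    _validate_table(table)
    return table
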