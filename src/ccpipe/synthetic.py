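"""Synthetic row-crop scenes with ground truth.

Every pipeline stage is testable without field imagery: this module renders
drilled-crop plots as seen from nadir — plant material accumulated as
jittered leaf blobs along evenly spaced rows over a soil background — and
returns the exact plant mask alongside the rendered image.

Color model (channel order R, G, B on [0, 1]): plants are bright in the
first channel (mean 0.75) to emulate a camera whose red channel was
converted to near-infrared, where vegetation reflects strongly, and dark in
blue (mean 0.15); soil is a desaturated brown (0.45, 0.40, 0.35). Gaussian
pixel noise (sd 0.03) is added throughout.

Illumination scenarios follow the two field conditions: LLC (low
light-contrast) scenes have a uniform illumination field, while HLC (high
light-contrast) scenes are multiplied by a smooth field with bright patches
that clip at 1.0 (at least 5 % of pixels saturated in some channel) and
shadow patches down to ≤ 0.3× brightness. The truth mask is frozen before
illumination is applied, so saturation and shadow create genuine
segmentation difficulty without corrupting the ground truth.

Time series follow per-plot logistic growth curves, emulating early canopy
development, and return the true CC table for parameter-recovery tests.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import disk

from .color_features import RGBImage

__all__ = [
    "GenerationError",
    "FieldScene",
    "SeriesSpec",
    "generate_field_image",
    "generate_series",
    "save_scene",
]

PLANT_COLOR = np.array([0.75, 0.50, 0.15])
SOIL_COLOR = np.array([0.45, 0.40, 0.35])
NOISE_SD = 0.03
_CC_TOL = 0.02  # achieved plant fraction must be within this of cc_target
_SATURATION_TARGET = 0.05  # HLC contract: >= 5 % saturated pixels


class GenerationError(RuntimeError):
    """Requested scene geometry is infeasible (cc_target unreachable)."""


@dataclass(frozen=True)
class FieldScene:
    """A rendered scene with its exact plant mask and generation metadata."""

    image: RGBImage
    truth: np.ndarray
    scenario: str
    row_count: int
    cc_true: float
    seed: int

    def __post_init__(self) -> None:
        if self.truth.shape != self.image.shape:
            raise ValueError("truth mask and image shapes differ")


def _grow_truth_mask(
    rng: np.random.Generator,
    shape: tuple[int, int],
    row_count: int,
    cc_target: float,
) -> np.ndarray:
    """Accumulate leaf blobs along row stripes until the target cover is hit."""
    h, w = shape
    truth = np.zeros(shape, dtype=bool)
    if cc_target == 0.0:
        return truth
    n_px = h * w
    spacing = w / row_count
    centers = (np.arange(row_count) + 0.5) * spacing
    half_width = 0.38 * spacing  # stripes cover ~76 % of the width at most

    max_blobs = 400 * n_px // 1000 + 10_000
    for _ in range(max_blobs):
        row = centers[rng.integers(row_count)]
        cx = row + rng.uniform(-half_width, half_width)
        cy = rng.uniform(0, h)
        radius = rng.integers(2, 6)
        rr, cc = disk((cy, cx), radius, shape=shape)
        truth[rr, cc] = True
        if truth.sum() / n_px >= cc_target:
            break
    achieved = truth.sum() / n_px
    if abs(achieved - cc_target) > _CC_TOL:
        raise GenerationError(
            f"cc_target {cc_target} unreachable with {row_count} rows on {shape} "
            f"(achieved {achieved:.3f})"
        )
    return truth


def _hlc_illumination(
    rng: np.random.Generator, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray, list]:
    """Smooth multiplicative field with bright and shadow patches.

    Returns the shadow-only component, the bright bump profiles and their
    random centers, so the caller can rescale brightness deterministically
    until the saturation contract is met.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    scale = min(h, w)

    bright_bumps = []
    for _ in range(rng.integers(2, 4)):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        sigma = rng.uniform(0.12, 0.22) * scale
        bright_bumps.append(np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)))

    shadow = np.ones(shape)
    for _ in range(rng.integers(1, 3)):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        sigma = rng.uniform(0.10, 0.18) * scale
        bump = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
        shadow *= 1.0 - 0.75 * bump  # <= 0.25x brightness in the core
    return shadow, bright_bumps, []


def _saturation_fraction(pixels: np.ndarray) -> float:
    levels = np.rint(pixels * 255.0)
    return float((levels >= 255).any(axis=2).mean())


def generate_field_image(
    scenario: str = "LLC",
    row_count: int = 8,
    cc_target: float = 0.3,
    size: tuple[int, int] = (160, 220),
    seed: int = 0,
    *,
    plot_id: str | None = None,
    date: _dt.date | None = None,
) -> FieldScene:
    """Render one nadir plot scene with ground truth.

    Parameters
    ----------
    scenario : {"LLC", "HLC"}
        Illumination scenario (see module docstring).
    row_count : int
        Number of vertical crop rows (>= 1).
    cc_target : float
        Requested plant fraction in [0, 0.95]; the achieved fraction lands
        within ±0.02 of it or a :class:`GenerationError` is raised.
    size : (H, W)
    seed : int
        Single seed for all randomness; identical calls are bit-identical.
    """
    if scenario not in ("LLC", "HLC"):
        raise ValueError(f"scenario must be LLC or HLC, got {scenario!r}")
    if not (0.0 <= cc_target <= 0.95):
        raise ValueError(f"cc_target must lie in [0, 0.95], got {cc_target}")
    if row_count < 1:
        raise ValueError("row_count must be >= 1")

    rng = np.random.default_rng(seed)
    h, w = size
    truth = _grow_truth_mask(rng, (h, w), row_count, cc_target)

    pixels = np.empty((h, w, 3))
    pixels[:] = SOIL_COLOR
    pixels[truth] = PLANT_COLOR
    pixels += rng.normal(0.0, NOISE_SD, size=pixels.shape)
    pixels = np.clip(pixels, 0.0, 1.0)

    if scenario == "HLC":
        shadow, bright_bumps, _ = _hlc_illumination(rng, (h, w))
        amp = 1.0
        for _ in range(30):
            fld = shadow * (1.0 + amp * sum(bright_bumps))
            lit = np.clip(pixels * fld[:, :, None], 0.0, 1.0)
            if _saturation_fraction(lit) >= _SATURATION_TARGET:
                break
            amp *= 1.4
        else:  # pragma: no cover - amp growth saturates any finite scene
            raise GenerationError("could not reach the HLC saturation target")
        pixels = lit

    image = RGBImage(pixels=pixels, plot_id=plot_id, date=date)
    return FieldScene(
        image=image,
        truth=truth.astype(np.uint8),
        scenario=scenario,
        row_count=row_count,
        cc_true=float(truth.mean()),
        seed=seed,
    )


@dataclass
class SeriesSpec:
    """Parameters of a synthetic measurement campaign.

    Per plot, canopy cover follows a logistic curve
    ``cc(t) = cc_max / (1 + exp(-rate * (t - midpoint)))`` in days since
    the first date. Plot parameters may be given explicitly (arrays of
    length ``n_plots``) or are drawn once from realistic ranges:
    cc_max ~ U(0.55, 0.85), midpoint ~ U(0.35, 0.65) of the campaign span,
    rate ~ U(0.10, 0.18) per day — an early-season wheat canopy reaching
    60–85 % cover. ``scenario_by_date`` assigns "LLC" or "HLC" per date
    (all LLC by default).
    """

    n_plots: int
    dates: list
    cc_max: np.ndarray | None = None
    midpoint: np.ndarray | None = None
    rate: np.ndarray | None = None
    scenario_by_date: dict | None = None
    row_count: int = 8
    size: tuple[int, int] = (160, 220)
    seed: int = 0


def generate_series(spec: SeriesSpec) -> tuple[list[FieldScene], pd.DataFrame]:
    """Render one scene per (plot, date) following the spec's growth curves.

    Returns the scenes (each image stamped with plot id and date) and the
    true CC table with columns ``plot_id, date, scenario, cc_curve,
    cc_true`` — ``cc_curve`` the logistic target, ``cc_true`` the achieved
    plant fraction of the rendered mask.
    """
    dates = list(spec.dates)
    if len(dates) < 1 or spec.n_plots < 1:
        raise ValueError("series needs at least one plot and one date")
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValueError("dates must be strictly increasing")

    rng = np.random.default_rng(spec.seed)
    span = max((dates[-1] - dates[0]).days, 1)
    cc_max = (
        np.asarray(spec.cc_max, dtype=float)
        if spec.cc_max is not None
        else rng.uniform(0.55, 0.85, spec.n_plots)
    )
    midpoint = (
        np.asarray(spec.midpoint, dtype=float)
        if spec.midpoint is not None
        else rng.uniform(0.35, 0.65, spec.n_plots) * span
    )
    rate = (
        np.asarray(spec.rate, dtype=float)
        if spec.rate is not None
        else rng.uniform(0.10, 0.18, spec.n_plots)
    )
    for name, arr in (("cc_max", cc_max), ("midpoint", midpoint), ("rate", rate)):
        if arr.shape != (spec.n_plots,):
            raise ValueError(f"{name} must have one value per plot")
        if not np.isfinite(arr).all():
            raise ValueError(f"{name} must be finite")

    scenario_by_date = spec.scenario_by_date or {}
    scenes: list[FieldScene] = []
    rows = []
    for p in range(spec.n_plots):
        plot_id = f"plot{p + 1:02d}"
        for d in dates:
            t = (d - dates[0]).days
            cc_curve = float(cc_max[p] / (1.0 + np.exp(-rate[p] * (t - midpoint[p]))))
            cc_curve = min(cc_curve, 0.9)
            scenario = scenario_by_date.get(d, "LLC")
            scene_seed = int(rng.integers(2**31))
            scene = generate_field_image(
                scenario=scenario,
                row_count=spec.row_count,
                cc_target=cc_curve,
                size=spec.size,
                seed=scene_seed,
                plot_id=plot_id,
                date=d,
            )
            scenes.append(scene)
            rows.append(
                {
                    "plot_id": plot_id,
                    "date": d,
                    "scenario": scenario,
                    "cc_curve": cc_curve,
                    "cc_true": scene.cc_true,
                }
            )
    return scenes, pd.DataFrame(rows)


def save_scene(scene: FieldScene, directory: str | Path, stem: str) -> dict:
    """Write a scene as image PNG + truth PNG (0/255) + metadata JSON.

    Returns a manifest row (path, plot_id, date, truth_path) for pipeline
    consumption.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    img_path = directory / f"{stem}.png"
    truth_path = directory / f"{stem}_truth.png"
    meta_path = directory / f"{stem}.json"

    iio.imwrite(img_path, np.clip(np.rint(scene.image.pixels * 255), 0, 255).astype(np.uint8))
    iio.imwrite(truth_path, (scene.truth * 255).astype(np.uint8))
    meta = {
        "scenario": scene.scenario,
        "row_count": scene.row_count,
        "cc_true": scene.cc_true,
        "seed": scene.seed,
        "plot_id": scene.image.plot_id,
        "date": scene.image.date.isoformat() if scene.image.date else None,
    }
    meta_path.write_text(json.dumps(meta, indent=2))
    return {
        "path": str(img_path),
        "plot_id": scene.image.plot_id or stem,
        "date": scene.image.date.isoformat() if scene.image.date else "",
        "truth_path": str(truth_path),
    }
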