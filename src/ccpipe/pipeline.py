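"""End-to-end orchestration: manifest in, CC table + QC report out.

The batch runs the three pipeline stages per image — (1) color/VI
conversion, (2) segmentation by thresholding, clustering or a routed
machine-learning model, (3) mask clean-up and canopy-cover computation —
then the time-series quality control over all records. A failed image is
logged and skipped, never aborting the batch: field campaigns contain
corrupt frames.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import eda as _eda
from .color_features import PRODUCT_VI_NAMES, VI_NAMES, RGBImage, compute_product_vi, compute_vi, load_image
from .illumination import IlluminationModel, classify_illumination
from .postprocess import CCRecord, canopy_cover, denoise_mask
from .segmentation import ModelBank, route_scenario, segment_kmeans, segment_supervised
from .thresholding import NoRowsDetectedError, apply_threshold, murow_threshold, otsu_threshold

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_manifest"]

logger = logging.getLogger(__name__)

_METHODS = ("otsu", "murow", "kmeans", "ml")


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run.

    ``method`` picks the segmentation route; ``vi`` the index plane used by
    the thresholding methods. ``illum_model`` (a path or a loaded
    :class:`IlluminationModel`) enables scenario classification; it is
    required for per-scenario routing of ``method="ml"`` (without it, the
    general ALC model is used). Post-processing parameters follow the
    printed defaults for full-resolution frames; scale ``min_object_px``
    with image area for smaller rasters.
    """

    method: str = "otsu"
    vi: str = "NDI3V"
    illum_model: object | None = None
    bank: object | None = None
    median_size: int = 5
    min_object_px: int = 400
    connectivity: int = 8
    roi: tuple | None = None
    row_axis: str = "auto"
    min_row_spacing_px: int = 12
    smooth_strength: float = 0.018
    murow_fallback_otsu: bool = True
    corr_method: str = "pearson"
    min_pairs: int = 3
    r_min: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if self.vi not in VI_NAMES + PRODUCT_VI_NAMES:
            raise ValueError(f"unknown VI {self.vi!r}")
        if isinstance(self.illum_model, (str, Path)):
            self.illum_model = IlluminationModel.load(self.illum_model)
        if isinstance(self.bank, (str, Path)):
            self.bank = ModelBank.load(self.bank)
        if self.method == "ml" and self.bank is None:
            raise ValueError("method 'ml' requires a model bank")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def echo(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            out[f.name] = v if isinstance(v, (str, int, float, bool, tuple, list, type(None))) else repr(v)
        return out


@dataclass
class PipelineResult:
    """Everything one batch produced, plus per-image failure reasons."""

    cc: pd.DataFrame
    records: list
    masks: dict
    corr: pd.DataFrame | None
    flags: list
    failures: list


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read an image manifest CSV (columns: path, plot_id, date ISO-8601)."""
    manifest = pd.read_csv(path, dtype={"plot_id": str})
    missing = [c for c in ("path", "plot_id", "date") if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest lacks columns {missing}")
    return manifest


def _vi_plane(img: RGBImage, name: str):
    if name in PRODUCT_VI_NAMES:
        return compute_product_vi(img, name)
    return compute_vi(img, name)


def segment_image(config: PipelineConfig, img: RGBImage, illum_class: int | None):
    """Apply the configured segmentation route to one image (raw mask)."""
    if config.method == "kmeans":
        return segment_kmeans(img, seed=config.seed)
    if config.method == "ml":
        if illum_class is None:
            model = config.bank.models.get("ALC")
            if model is None:
                raise ValueError("no illumination label and no ALC model in bank")
        else:
            model = route_scenario(config.bank, illum_class)
        return segment_supervised(model, img)

    vi = _vi_plane(img, config.vi)
    if config.method == "murow":
        try:
            res = murow_threshold(
                vi,
                row_axis=config.row_axis,
                min_row_spacing_px=config.min_row_spacing_px,
                smooth_strength=config.smooth_strength,
            )
        except NoRowsDetectedError:
            if not config.murow_fallback_otsu:
                raise
            logger.warning("no rows detected; falling back to Otsu")
            res = otsu_threshold(vi)
    else:
        res = otsu_threshold(vi)
    return apply_threshold(vi, res.threshold)


def run_pipeline(
    config: PipelineConfig,
    manifest: pd.DataFrame,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full pipeline over an image manifest.

    Parameters
    ----------
    config
    manifest : DataFrame
        Columns ``path, plot_id, date``; one row per image.
    out_dir : optional
        When given, masks (``<stem>_mask.png``), ``cc.csv``, ``corr.csv``,
        ``flags.csv``, the effective config and a plain-text QC report are
        written there.

    Raises
    ------
    RuntimeError
        Empty manifest, or every single image failed.
    """
    if len(manifest) == 0:
        raise RuntimeError("empty manifest")

    records: list[CCRecord] = []
    rows = []
    masks: dict[str, np.ndarray] = {}
    failures: list[dict] = []

    for entry in manifest.itertuples(index=False):
        try:
            img = load_image(entry.path, plot_id=str(entry.plot_id), date=str(entry.date))
            illum_class = (
                classify_illumination(config.illum_model, img)
                if config.illum_model is not None
                else None
            )
            raw = segment_image(config, img, illum_class)
            mask = denoise_mask(
                raw,
                median_size=config.median_size,
                min_object_px=config.min_object_px,
                connectivity=config.connectivity,
            )
            rec = canopy_cover(
                mask,
                roi=config.roi,
                plot_id=img.plot_id,
                date=img.date,
                illumination_class=illum_class,
                method=config.method,
            )
        except Exception as exc:  # noqa: BLE001 - per-image isolation is the contract
            logger.warning("image %s failed: %s", entry.path, exc)
            failures.append({"path": entry.path, "error": str(exc)})
            continue
        records.append(rec)
        stem = Path(entry.path).stem
        masks[stem] = mask
        rows.append(
            {
                "path": entry.path,
                "plot_id": rec.plot_id,
                "date": rec.date,
                "cc": rec.cc,
                "illumination_class": rec.illumination_class,
                "n_plant_px": rec.n_plant_px,
                "n_total_px": rec.n_total_px,
                "method": rec.method,
            }
        )

    if not records:
        raise RuntimeError(f"all {len(manifest)} images failed; first error: {failures[0]['error']}")

    cc = pd.DataFrame(rows).sort_values(["plot_id", "date"], kind="stable").reset_index(drop=True)

    corr = None
    flags: list = []
    try:
        matrix = _eda.build_cc_matrix(records)
        corr = _eda.date_correlation_matrix(matrix, method=config.corr_method, min_pairs=config.min_pairs)
        flags = _eda.flag_outlier_dates(corr, r_min=config.r_min)
    except ValueError as exc:
        logger.info("EDA skipped: %s", exc)

    result = PipelineResult(cc=cc, records=records, masks=masks, corr=corr, flags=flags, failures=failures)
    if out_dir is not None:
        _write_outputs(config, result, Path(out_dir))
    return result


def _write_outputs(config: PipelineConfig, result: PipelineResult, out_dir: Path) -> None:
    import imageio.v3 as iio

    out_dir.mkdir(parents=True, exist_ok=True)
    result.cc.to_csv(out_dir / "cc.csv", index=False, float_format="%.6f")
    if result.corr is not None:
        result.corr.to_csv(out_dir / "corr.csv", float_format="%.6f")
    pd.DataFrame(
        [{"date": f.date, "r_prev": f.r_prev, "r_next": f.r_next} for f in result.flags]
    ).to_csv(out_dir / "flags.csv", index=False)
    for stem, mask in result.masks.items():
        iio.imwrite(out_dir / f"{stem}_mask.png", (mask * 255).astype(np.uint8))
    (out_dir / "config.yaml").write_text(yaml.safe_dump(config.echo(), sort_keys=True))

    lines = [
        f"images processed: {len(result.records)}",
        f"images failed:    {len(result.failures)}",
        f"flagged dates:    {[str(f.date) for f in result.flags] or 'none'}",
    ]
    for fail in result.failures:
        lines.append(f"FAILED {fail['path']}: {fail['error']}")
    (out_dir / "qc_report.txt").write_text("\n".join(lines) + "\n")
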