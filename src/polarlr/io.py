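"""File formats and run configuration.

Conventions: CSV is UTF-8, comma-separated with a header row and '.' decimal;
pixel coordinates are 0-based half-open everywhere.  Intensity stacks are
multi-page TIFF (one page per acquisition state, page order = manifest order)
with a JSON manifest sidecar; Mueller images are NPZ arrays of shape
(4, 4, H, W) with a JSON metadata blob.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .decomposition import FEATURE_NAMES
from .optics import IntensityStack, PolStateSequence, centroid_drift
from .roi import ROIDefinition

__all__ = [
    "RunConfig",
    "load_config",
    "write_stack",
    "read_stack",
    "write_mueller_image",
    "read_mueller_image",
    "write_features",
    "read_features",
    "write_rois",
    "read_rois",
    "write_patients",
    "read_patients",
    "write_report",
]

_DRIFT_WARN_PX = 2.0


# ---------------------------------------------------------------------------
# run configuration (schema-validated; unknown keys rejected)


class ClassParamsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    retardance_mean: float
    diattenuation_mean: float
    depolarization_mean: float
    retardance_sd: tuple[float, float, float] = (0.10, 0.05, 0.15)
    diattenuation_sd: tuple[float, float, float] = (0.03, 0.02, 0.04)
    depolarization_sd: tuple[float, float, float] = (0.05, 0.03, 0.06)
    orientation_pixel_sd_deg: float = 10.0


class CohortSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_patients: tuple[int, int] = (27, 8)
    rois_per_patient: tuple[int, int] = (3, 14)
    use_study_roi_counts: bool = False
    pixels_per_roi: int = 2500
    n_outlier_patients: int = 0


class ExperimentSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    models: list[str] = ["logistic", "lda", "svm", "random_forest", "xgboost"]
    k: int = 5
    top_k: int = 5
    vote_threshold: float = 0.5
    outlier_budget: int = 0
    outlier_tol: float = 0.005
    outlier_model: str = "xgboost"
    feature_subset: Optional[list[str]] = None
    t_stage_subgroup: Optional[int] = 3


class RunConfig(BaseModel):
    """Top-level run configuration; validated before any stage runs."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    cohort: CohortSection = CohortSection()
    class_params: Optional[dict[Literal["no_lr", "lr"], ClassParamsConfig]] = None
    experiment: ExperimentSection = ExperimentSection()

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text()) or {}
        return RunConfig.model_validate(data)
    except ValidationError as e:
        first = e.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ValueError(f"invalid config {path}: field '{loc}': {first['msg']}") from e


# ---------------------------------------------------------------------------
# intensity stacks


def write_stack(stack: IntensityStack, tiff_path: str | Path) -> None:
    """Multi-page TIFF (float32) + '<stem>.manifest.json' sidecar."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, stack.frames.astype(np.float32))
    manifest_path = tiff_path.with_suffix(".manifest.json")
    manifest_path.write_text(stack.manifest.to_json())


def read_stack(tiff_path: str | Path) -> IntensityStack:
    tiff_path = Path(tiff_path)
    frames = tifffile.imread(tiff_path)
    if frames.ndim == 2:
        frames = frames[None]
    manifest_path = tiff_path.with_suffix(".manifest.json")
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest sidecar missing for {tiff_path}: {manifest_path}")
    manifest = PolStateSequence.from_json(manifest_path.read_text())
    if frames.shape[0] != len(manifest):
        raise ValueError(
            f"{tiff_path}: page count {frames.shape[0]} != manifest length {len(manifest)}"
        )
    drift = centroid_drift(frames)
    if drift > _DRIFT_WARN_PX:
        warnings.warn(
            f"{tiff_path}: intensity centroid drifts {drift:.1f} px between frames; "
            "stack may not be registered",
            stacklevel=2,
        )
    return IntensityStack(np.asarray(frames, dtype=float), manifest)


# ---------------------------------------------------------------------------
# Mueller images


def write_mueller_image(
    path: str | Path, mm: np.ndarray, normalized: bool = False, manifest_hash: str = ""
) -> None:
    if mm.ndim != 4 or mm.shape[:2] != (4, 4):
        raise ValueError(f"Mueller image must be (4, 4, H, W), got {mm.shape}")
    meta = json.dumps({"normalized": normalized, "manifest_hash": manifest_hash})
    np.savez(path, mm=mm, meta=np.array(meta))


def read_mueller_image(path: str | Path) -> tuple[np.ndarray, dict]:
    with np.load(path) as z:
        mm = z["mm"]
        meta = json.loads(str(z["meta"]))
    return mm, meta


# ---------------------------------------------------------------------------
# tables


def write_features(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in ("roi_id", "patient_id", "label", *FEATURE_NAMES) if c not in df.columns]
    if missing:
        raise ValueError(f"features table missing columns {missing}")
    df.to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"roi_id": str, "patient_id": str})
    missing = [c for c in ("roi_id", "patient_id", "label", *FEATURE_NAMES) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: features CSV missing columns {missing}")
    return df


def write_rois(rois: list[ROIDefinition], path: str | Path) -> None:
    rows = [
        {
            "roi_id": r.roi_id,
            "patient_id": r.patient_id,
            "label": r.label,
            "x0": r.rect[0],
            "y0": r.rect[1],
            "x1": r.rect[2],
            "y1": r.rect[3],
        }
        for r in rois
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rois(path: str | Path) -> list[ROIDefinition]:
    df = pd.read_csv(path, dtype={"roi_id": str, "patient_id": str})
    required = {"roi_id", "patient_id", "label", "x0", "y0", "x1", "y1"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: ROI CSV missing columns {sorted(missing)}")
    return [
        ROIDefinition(
            roi_id=row.roi_id,
            patient_id=row.patient_id,
            label=int(row.label),
            rect=(int(row.x0), int(row.y0), int(row.x1), int(row.y1)),
        )
        for row in df.itertuples()
    ]


def write_patients(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_patients(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = {"patient_id", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: patients CSV missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# reports


def _jsonable(obj):
    import dataclasses

    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(report: dict, path: str | Path, config_hash: str = "", version: str = "") -> None:
    """Serialize a workflow result to JSON (fold arrays included, NaN → null)."""
    payload = {"polarlr_version": version, "config_hash": config_hash}
    payload.update(_jsonable(report))
    Path(path).write_text(json.dumps(payload, indent=1, allow_nan=False))
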