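"""ROI-level aggregation: per-pixel Mueller images → one feature record per ROI.

Aggregation happens *before* feature extraction: the 16 Mueller elements are
reduced to their element-wise median over the ROI's pixels (robust to
outlier pixels), and the 25 features are then computed on that single median
matrix.  The reverse order (per-pixel features, then median) gives different
numbers on heterogeneous tissue and is deliberately not what this module does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decomposition import FEATURE_NAMES, feature_vector

__all__ = ["ROIDefinition", "MedianMM", "median_mueller", "roi_feature_record", "feature_table"]


@dataclass(frozen=True)
class ROIDefinition:
    """One pathologist ROI: a labelled axis-aligned pixel rectangle.

    ``rect`` is (x0, y0, x1, y1), 0-based half-open; ``label`` is the binary
    5-year local-recurrence status (0 = no-LR, 1 = LR).
    """

    roi_id: str
    patient_id: str
    label: int
    rect: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        x0, y0, x1, y1 = self.rect
        if not (x1 > x0 and y1 > y0):
            raise ValueError(f"empty ROI rectangle {self.rect}")

    def slices(self) -> tuple[slice, slice]:
        x0, y0, x1, y1 = self.rect
        return slice(y0, y1), slice(x0, x1)


@dataclass(frozen=True)
class MedianMM:
    """Element-wise median Mueller matrix over an ROI's unmasked pixels."""

    m: np.ndarray
    n_pixels: int


def median_mueller(mm_image: np.ndarray, roi: ROIDefinition) -> MedianMM:
    """Element-wise median over the ROI, excluding NaN-masked pixels.

    ``mm_image`` has shape (4, 4, H, W).  A pixel is excluded if any of its
    16 elements is NaN.  Deterministic; even pixel counts use the mean of the
    two middle values.
    """
    if mm_image.ndim != 4 or mm_image.shape[:2] != (4, 4):
        raise ValueError(f"mm_image must have shape (4, 4, H, W), got {mm_image.shape}")
    h, w = mm_image.shape[2:]
    x0, y0, x1, y1 = roi.rect
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        raise ValueError(f"ROI {roi.roi_id} rect {roi.rect} outside image bounds {(w, h)}")
    ys, xs = roi.slices()
    region = mm_image[:, :, ys, xs].reshape(16, -1)
    valid = ~np.any(np.isnan(region), axis=0)
    n = int(valid.sum())
    if n == 0:
        raise ValueError(f"ROI {roi.roi_id} has no unmasked pixels")
    med = np.median(region[:, valid], axis=1).reshape(4, 4)
    return MedianMM(m=med, n_pixels=n)


def roi_feature_record(mm_image: np.ndarray, roi: ROIDefinition) -> dict:
    """25 features of the ROI's median Mueller matrix, plus identifying metadata.

    Any decomposition warning flags are carried through in the ``flags`` field.
    """
    med = median_mueller(mm_image, roi)
    fv = feature_vector(med.m)
    rec = {
        "roi_id": roi.roi_id,
        "patient_id": roi.patient_id,
        "label": roi.label,
        "n_pixels": med.n_pixels,
        "flags": ";".join(fv.flags),
    }
    rec.update({name: fv[name] for name in FEATURE_NAMES})
    return rec


def feature_table(mm_images: dict[str, np.ndarray], rois: list[ROIDefinition]) -> pd.DataFrame:
    """Feature records for many ROIs; ``mm_images`` maps roi_id → (4,4,H,W) image.

    ROIs whose id is missing from ``mm_images`` raise, never silently drop.
    """
    records = []
    for roi in rois:
        if roi.roi_id not in mm_images:
            raise KeyError(f"no Mueller image for ROI {roi.roi_id}")
        records.append(roi_feature_record(mm_images[roi.roi_id], roi))
    return pd.DataFrame(records)
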