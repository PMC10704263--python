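"""Synthetic two-class polarimetric tissue cohorts.

Emulates the statistical structure the analysis assumes, with no claim of
image realism: each pixel of collagenous stroma is a physical Mueller matrix
composed as depolarizer · retarder · diattenuator, with class-conditional
retardance, diattenuation and depolarization drawn hierarchically
(class → patient → ROI → pixel) and uniformly random fiber orientation.
Patients that did not locally recur (mature stroma) default to higher linear
retardance and diattenuation and lower depolarization than recurring
patients (immature stroma); the magnitudes are configuration, not claims
about real tissue.

The cohort shape mirrors the study setting: 27 no-LR vs 8 LR patients with
3–14 ROIs each, optionally pinned to exactly 263/70 ROIs, plus optional
planted "outlier" patients whose labels are flipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decomposition import FEATURE_NAMES, feature_vector
from .optics import (
    IntensityStack,
    PolStateSequence,
    isotropic_depolarizer,
    linear_diattenuator,
    linear_retarder,
)

__all__ = [
    "TissueClassParams",
    "CohortConfig",
    "default_class_params",
    "null_class_params",
    "separable_class_params",
    "study_roi_counts",
    "sample_pixel_mueller",
    "sample_pixel_muellers",
    "generate_cohort",
    "roi_intensity_stack",
]


@dataclass(frozen=True)
class TissueClassParams:
    """Class-conditional distributions of the generating tissue parameters.

    Means are class-level; the three sd tiers model between-patient,
    between-ROI and between-pixel variability.  Gaussian families throughout,
    clipped to the physical ranges δ ∈ [0, π], D ∈ [0, 0.95], Δ ∈ [0, 1].
    Fiber orientation is uniform on [0°, 180°) per ROI with a small per-pixel
    wobble.
    """

    retardance_mean: float  # rad
    diattenuation_mean: float
    depolarization_mean: float
    retardance_sd: tuple[float, float, float] = (0.10, 0.05, 0.15)
    diattenuation_sd: tuple[float, float, float] = (0.03, 0.02, 0.04)
    depolarization_sd: tuple[float, float, float] = (0.05, 0.03, 0.06)
    orientation_pixel_sd_deg: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.retardance_mean <= np.pi:
            raise ValueError(f"retardance mean outside [0, pi]: {self.retardance_mean}")
        if not 0.0 <= self.diattenuation_mean < 1.0:
            raise ValueError(f"diattenuation mean outside [0, 1): {self.diattenuation_mean}")
        if not 0.0 <= self.depolarization_mean <= 1.0:
            raise ValueError(f"depolarization mean outside [0, 1]: {self.depolarization_mean}")
        for sds in (self.retardance_sd, self.diattenuation_sd, self.depolarization_sd):
            if any(s < 0 for s in sds):
                raise ValueError(f"negative sd in {sds}")


def default_class_params() -> dict[int, TissueClassParams]:
    """Default class contrast: mature (no-LR) vs immature (LR) stroma."""
    return {
        0: TissueClassParams(
            retardance_mean=0.80, diattenuation_mean=0.12, depolarization_mean=0.30
        ),
        1: TissueClassParams(
            retardance_mean=0.50, diattenuation_mean=0.06, depolarization_mean=0.45
        ),
    }


def null_class_params() -> dict[int, TissueClassParams]:
    """Identical class distributions — no signal; used for null calibration."""
    p = TissueClassParams(
        retardance_mean=0.65, diattenuation_mean=0.09, depolarization_mean=0.38
    )
    return {0: p, 1: p}


def separable_class_params() -> dict[int, TissueClassParams]:
    """Large class separation in retardance and diattenuation (power checks)."""
    tight = dict(
        retardance_sd=(0.04, 0.02, 0.08),
        diattenuation_sd=(0.01, 0.01, 0.02),
        depolarization_sd=(0.03, 0.02, 0.04),
    )
    return {
        0: TissueClassParams(
            retardance_mean=1.10, diattenuation_mean=0.20, depolarization_mean=0.20, **tight
        ),
        1: TissueClassParams(
            retardance_mean=0.35, diattenuation_mean=0.04, depolarization_mean=0.55, **tight
        ),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Shape of the generated cohort."""

    n_patients: tuple[int, int] = (27, 8)  # (no-LR, LR)
    rois_per_patient: tuple[int, int] = (3, 14)  # inclusive uniform range
    roi_counts: tuple[tuple[int, ...], tuple[int, ...]] | None = None  # explicit override
    pixels_per_roi: int = 2500
    n_outlier_patients: int = 0
    t_stage3_fraction: tuple[float, float] = (21 / 27, 3 / 8)  # per class
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_patients):
            raise ValueError(f"patient counts must be positive: {self.n_patients}")
        lo, hi = self.rois_per_patient
        if not (1 <= lo <= hi):
            raise ValueError(f"bad ROI range {self.rois_per_patient}")
        if self.pixels_per_roi <= 0:
            raise ValueError("pixels_per_roi must be positive")
        if self.n_outlier_patients < 0 or self.n_outlier_patients >= self.n_patients[0]:
            raise ValueError(
                f"n_outlier_patients must be in [0, n_no_lr): {self.n_outlier_patients}"
            )
        if self.roi_counts is not None:
            for cls, counts in enumerate(self.roi_counts):
                if len(counts) != self.n_patients[cls]:
                    raise ValueError(
                        f"roi_counts[{cls}] has {len(counts)} entries for "
                        f"{self.n_patients[cls]} patients"
                    )


def study_roi_counts() -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Per-patient ROI counts reproducing the study totals 263 (no-LR) + 70 (LR).

    Counts stay within the observed 3–14 range; the spread is deterministic.
    """
    no_lr = _spread_counts(total=263, n=27, lo=3, hi=14)
    lr = _spread_counts(total=70, n=8, lo=3, hi=14)
    return tuple(no_lr), tuple(lr)


def _spread_counts(total: int, n: int, lo: int, hi: int) -> list[int]:
    base, extra = divmod(total, n)
    counts = [base + 1] * extra + [base] * (n - extra)
    # deterministic zig-zag within bounds so counts are not all-equal
    for i in range(0, n - 1, 2):
        shift = min(hi - counts[i], counts[i + 1] - lo, (i // 2) % 4)
        counts[i] += shift
        counts[i + 1] -= shift
    assert sum(counts) == total and all(lo <= c <= hi for c in counts)
    return counts


# ---------------------------------------------------------------------------
# pixel-level sampling


def sample_pixel_muellers(
    n: int,
    retardance: np.ndarray | float,
    orientation_deg: np.ndarray | float,
    diattenuation: np.ndarray | float,
    depolarization: np.ndarray | float,
) -> np.ndarray:
    """Vectorized composition M = M_Δ(Δ) · M_R(δ, θ) · M_D(D, θ) → (n, 4, 4).

    The diattenuator axis is aligned with the retarder fast axis: both arise
    from the same fiber population.
    """
    delta = np.broadcast_to(np.asarray(retardance, dtype=float), (n,))
    theta = np.deg2rad(np.broadcast_to(np.asarray(orientation_deg, dtype=float), (n,)))
    dia = np.broadcast_to(np.asarray(diattenuation, dtype=float), (n,))
    dep = np.broadcast_to(np.asarray(depolarization, dtype=float), (n,))

    c, s = np.cos(2 * theta), np.sin(2 * theta)
    cd, sd = np.cos(delta), np.sin(delta)
    ret = np.zeros((n, 4, 4))
    ret[:, 0, 0] = 1.0
    ret[:, 1, 1] = c * c + s * s * cd
    ret[:, 1, 2] = c * s * (1 - cd)
    ret[:, 1, 3] = -s * sd
    ret[:, 2, 1] = c * s * (1 - cd)
    ret[:, 2, 2] = s * s + c * c * cd
    ret[:, 2, 3] = c * sd
    ret[:, 3, 1] = s * sd
    ret[:, 3, 2] = -c * sd
    ret[:, 3, 3] = cd

    a = np.sqrt(np.clip(1.0 - dia * dia, 0.0, None))
    dx, dy = dia * c, dia * s
    mdia = np.zeros((n, 4, 4))
    mdia[:, 0, 0] = 1.0
    mdia[:, 0, 1] = dx
    mdia[:, 0, 2] = dy
    mdia[:, 1, 0] = dx
    mdia[:, 2, 0] = dy
    with np.errstate(invalid="ignore", divide="ignore"):
        one_minus_a = np.where(dia > 0, (1 - a) / np.where(dia > 0, dia * dia, 1.0), 0.0)
    mdia[:, 1, 1] = a + one_minus_a * dx * dx
    mdia[:, 1, 2] = one_minus_a * dx * dy
    mdia[:, 2, 1] = one_minus_a * dx * dy
    mdia[:, 2, 2] = a + one_minus_a * dy * dy
    mdia[:, 3, 3] = a

    m = np.einsum("nij,njk->nik", ret, mdia)
    scale = (1.0 - dep)[:, None]
    m[:, 1:, :] *= scale[..., None]
    return m


def sample_pixel_mueller(
    params: TissueClassParams, rng: np.random.Generator
) -> np.ndarray:
    """One pixel Mueller matrix with all parameters at their class means plus
    total (quadrature-combined) variability; orientation uniform."""
    sd = lambda t: float(np.sqrt(np.sum(np.square(t))))
    delta = float(np.clip(rng.normal(params.retardance_mean, sd(params.retardance_sd)), 0, np.pi))
    dia = float(np.clip(rng.normal(params.diattenuation_mean, sd(params.diattenuation_sd)), 0, 0.95))
    dep = float(np.clip(rng.normal(params.depolarization_mean, sd(params.depolarization_sd)), 0, 1))
    theta = float(rng.uniform(0, 180))
    return sample_pixel_muellers(1, delta, theta, dia, dep)[0]


# ---------------------------------------------------------------------------
# cohort generation


def _roi_pixel_matrices(
    n_pixels: int,
    roi_means: dict[str, float],
    params: TissueClassParams,
    rng: np.random.Generator,
) -> np.ndarray:
    delta = np.clip(
        rng.normal(roi_means["retardance"], params.retardance_sd[2], n_pixels), 0, np.pi
    )
    dia = np.clip(
        rng.normal(roi_means["diattenuation"], params.diattenuation_sd[2], n_pixels), 0, 0.95
    )
    dep = np.clip(
        rng.normal(roi_means["depolarization"], params.depolarization_sd[2], n_pixels), 0, 1
    )
    theta = rng.normal(roi_means["orientation"], params.orientation_pixel_sd_deg, n_pixels)
    return sample_pixel_muellers(n_pixels, delta, theta, dia, dep)


def generate_cohort(
    config: CohortConfig,
    class_params: dict[int, TissueClassParams] | None = None,
    return_pixel_matrices: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate a full cohort feature table.

    Returns ``(features, patients, truth)``:

    * ``features`` — one row per ROI: patient_id, roi_id, label, n_pixels,
      flags and the 25 features of the ROI's median Mueller matrix;
    * ``patients`` — patient_id, label, t_stage;
    * ``truth`` — ground-truth sidecar: per-ROI generating parameters and the
      list of planted label-flipped patients (empty when none are planted).

    Identical seeds give identical tables.
    """
    params = class_params or default_class_params()
    rng = np.random.default_rng(config.seed)
    feature_rows, patient_rows = [], []
    truth: dict = {"rois": {}, "outlier_patients": [], "seed": config.seed}
    pixel_store: dict[str, np.ndarray] = {}

    lo, hi = config.rois_per_patient
    counter = 0
    for cls in (0, 1):
        p = params[cls]
        for i in range(config.n_patients[cls]):
            pid = f"P{counter:03d}"
            counter += 1
            if config.roi_counts is not None:
                n_rois = config.roi_counts[cls][i]
            else:
                n_rois = int(rng.integers(lo, hi + 1))
            pat_means = {
                "retardance": float(
                    np.clip(rng.normal(p.retardance_mean, p.retardance_sd[0]), 0, np.pi)
                ),
                "diattenuation": float(
                    np.clip(rng.normal(p.diattenuation_mean, p.diattenuation_sd[0]), 0, 0.95)
                ),
                "depolarization": float(
                    np.clip(rng.normal(p.depolarization_mean, p.depolarization_sd[0]), 0, 1)
                ),
            }
            t3 = rng.uniform() < config.t_stage3_fraction[cls]
            t_stage = 3 if t3 else int(rng.choice([1, 2, 4]))
            patient_rows.append({"patient_id": pid, "label": cls, "t_stage": t_stage})
            for r in range(n_rois):
                roi_id = f"{pid}_R{r:02d}"
                roi_means = {
                    "retardance": float(
                        np.clip(
                            rng.normal(pat_means["retardance"], p.retardance_sd[1]), 0, np.pi
                        )
                    ),
                    "diattenuation": float(
                        np.clip(
                            rng.normal(pat_means["diattenuation"], p.diattenuation_sd[1]),
                            0,
                            0.95,
                        )
                    ),
                    "depolarization": float(
                        np.clip(
                            rng.normal(pat_means["depolarization"], p.depolarization_sd[1]),
                            0,
                            1,
                        )
                    ),
                    "orientation": float(rng.uniform(0, 180)),
                }
                pix = _roi_pixel_matrices(config.pixels_per_roi, roi_means, p, rng)
                med = np.median(pix.reshape(config.pixels_per_roi, 16), axis=0).reshape(4, 4)
                fv = feature_vector(med)
                row = {
                    "roi_id": roi_id,
                    "patient_id": pid,
                    "label": cls,
                    "n_pixels": config.pixels_per_roi,
                    "flags": ";".join(fv.flags),
                }
                row.update({n: fv[n] for n in FEATURE_NAMES})
                feature_rows.append(row)
                truth["rois"][roi_id] = roi_means
                if return_pixel_matrices:
                    pixel_store[roi_id] = pix

    features = pd.DataFrame(feature_rows)
    patients = pd.DataFrame(patient_rows)

    if config.n_outlier_patients:
        no_lr = patients[patients["label"] == 0]["patient_id"].tolist()
        flipped = no_lr[-config.n_outlier_patients :]
        features.loc[features["patient_id"].isin(flipped), "label"] = 1
        patients.loc[patients["patient_id"].isin(flipped), "label"] = 1
        truth["outlier_patients"] = flipped

    if return_pixel_matrices:
        truth["pixel_matrices"] = pixel_store
    return features, patients, truth


def roi_intensity_stack(
    pixel_matrices: np.ndarray,
    seq: PolStateSequence | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    shape: tuple[int, int] | None = None,
) -> IntensityStack:
    """Render an ROI's pixel Mueller matrices as a raw acquisition stack.

    ``pixel_matrices`` is (n_pixels, 4, 4); pixels are laid out on a
    near-square grid (padded with the last pixel) unless ``shape`` is given.
    """
    seq = seq or PolStateSequence.default()
    n = pixel_matrices.shape[0]
    if shape is None:
        h = int(np.ceil(np.sqrt(n)))
        shape = (h, int(np.ceil(n / h)))
    h, w = shape
    if h * w < n:
        raise ValueError(f"shape {shape} too small for {n} pixels")
    padded = np.concatenate(
        [pixel_matrices, np.repeat(pixel_matrices[-1:], h * w - n, axis=0)], axis=0
    )
    design = seq.design_matrix()  # (n_states, 16)
    frames = (design @ padded.reshape(h * w, 16).T).reshape(len(seq), h, w)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        scale = noise_sd * float(np.mean(np.abs(frames)))
        frames = frames + rng.normal(0.0, scale, size=frames.shape)
    return IntensityStack(frames, seq)
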