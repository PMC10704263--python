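"""Polarimetric parameter extraction from a Mueller matrix.

Three families of derived parameters are computed on the m00-normalized
matrix:

* Lu–Chipman polar decomposition ``M = M_Δ · M_R · M_D`` into a depolarizer,
  a retarder and a diattenuator, yielding diattenuation D, polarizance P,
  depolarization power Δ, total retardance R, linear retardance δ_L and
  optical rotation ψ.
* Mueller-matrix transformation (MMT) parameters b, t1 and the normalized
  anisotropy A, rotation-insensitive combinations of the central elements.
* The 16 normalized matrix elements themselves.

Together these give the 25-element feature vector used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics import MuellerMatrix, diattenuator_from_vector

__all__ = [
    "FEATURE_NAMES",
    "LuChipmanResult",
    "MMTParams",
    "FeatureVector",
    "diattenuation",
    "polarizance",
    "lu_chipman",
    "mmt_params",
    "feature_vector",
]

_ELEMENT_NAMES = [f"m{i}{j}" for i in range(4) for j in range(4)]
_DERIVED_NAMES = ["D", "P_L", "Delta", "R", "delta_L", "psi", "b", "t1", "A"]
#: Canonical order of the 25 polarimetric features.
FEATURE_NAMES: list[str] = _ELEMENT_NAMES + _DERIVED_NAMES

_D_SINGULAR = 1.0 - 1e-6


def _as_array(M: MuellerMatrix | np.ndarray) -> np.ndarray:
    arr = M.m if isinstance(M, MuellerMatrix) else np.asarray(M, dtype=float)
    if arr.shape != (4, 4):
        raise ValueError(f"expected 4x4 matrix, got shape {arr.shape}")
    if arr[0, 0] <= 0:
        raise ValueError(f"m00 must be > 0, got {arr[0, 0]}")
    return arr


def _clip_unit(x: float) -> float:
    # floating-point overshoot guard for arccos arguments and bounded ratios
    return float(np.clip(x, -1.0, 1.0))


def diattenuation(M: MuellerMatrix | np.ndarray) -> tuple[np.ndarray, float, float]:
    """Diattenuation vector, total D and linear D_L from the first row."""
    m = _as_array(M)
    d_vec = m[0, 1:] / m[0, 0]
    d = min(float(np.linalg.norm(d_vec)), 1.0)
    d_l = min(float(np.hypot(d_vec[0], d_vec[1])), d)
    return d_vec, d, d_l


def polarizance(M: MuellerMatrix | np.ndarray) -> tuple[np.ndarray, float, float]:
    """Polarizance vector, total P and linear P_L from the first column."""
    m = _as_array(M)
    p_vec = m[1:, 0] / m[0, 0]
    p = min(float(np.linalg.norm(p_vec)), 1.0)
    p_l = min(float(np.hypot(p_vec[0], p_vec[1])), p)
    return p_vec, p, p_l


@dataclass
class LuChipmanResult:
    """Outputs of the sequential polar decomposition M = M_Δ·M_R·M_D."""

    D_vec: np.ndarray
    D: float
    D_L: float
    P_vec: np.ndarray
    P: float
    P_L: float
    M_D: np.ndarray
    M_R: np.ndarray
    M_Delta: np.ndarray
    R: float
    delta_L: float
    psi: float
    Delta: float
    flags: list[str] = field(default_factory=list)

    def reconstruct(self) -> np.ndarray:
        return self.M_Delta @ self.M_R @ self.M_D


def lu_chipman(M: MuellerMatrix | np.ndarray) -> LuChipmanResult:
    """Sequential Lu–Chipman polar decomposition of a (normalized) Mueller matrix.

    The diattenuator factor is built from the first row; the depolarizer 3×3
    block is the signed symmetric square root of m'·m'ᵀ (eigenvalues clipped at
    zero, sign from det m'); the retarder is what remains.  A diattenuation at
    the singular limit D → 1 is clipped to 1−1e-6 and flagged rather than
    allowed to make M_D non-invertible.
    """
    m = _as_array(M)
    m = m / m[0, 0]
    flags: list[str] = []

    d_vec, d, d_l = diattenuation(m)
    p_vec, p, p_l = polarizance(m)

    if d >= _D_SINGULAR:
        flags.append("singular_diattenuator")
        d_vec = d_vec * (_D_SINGULAR / d)
        d = _D_SINGULAR
        d_l = float(np.hypot(d_vec[0], d_vec[1]))

    m_d = diattenuator_from_vector(d_vec)
    m_prime = m @ np.linalg.inv(m_d)

    sub = m_prime[1:, 1:]
    sym = sub @ sub.T
    lam, vec = np.linalg.eigh(sym)
    lam = np.clip(lam, 0.0, None)
    m_delta_sub = vec @ np.diag(np.sqrt(lam)) @ vec.T
    det = np.linalg.det(sub)
    if det < 0:
        m_delta_sub = -m_delta_sub
    # depolarizer polarizance vector
    m33 = m[1:, 1:]
    p_delta = (p_vec - m33 @ d_vec) / max(1.0 - d * d, 1e-12)

    m_delta = np.eye(4)
    m_delta[1:, 0] = p_delta
    m_delta[1:, 1:] = m_delta_sub

    if np.linalg.matrix_rank(m_delta_sub) < 3:
        flags.append("singular_depolarizer")
        sub_r = np.linalg.pinv(m_delta_sub) @ sub
    else:
        sub_r = np.linalg.solve(m_delta_sub, sub)
    m_r = np.eye(4)
    m_r[1:, 1:] = sub_r

    r_tot = float(np.arccos(_clip_unit(np.trace(m_r) / 2.0 - 1.0)))
    # linear retardance / rotation from the upper-left 2x2 of the 3x3 block
    a11, a22 = sub_r[0, 0], sub_r[1, 1]
    a21, a12 = sub_r[1, 0], sub_r[0, 1]
    delta_l = float(np.arccos(_clip_unit(np.hypot(a11 + a22, a21 - a12) - 1.0)))
    psi = 0.5 * float(np.arctan2(a21 - a12, a11 + a22))
    delta_cap = float(np.clip(1.0 - np.abs(np.trace(m_delta_sub)) / 3.0, 0.0, 1.0))

    return LuChipmanResult(
        D_vec=d_vec,
        D=d,
        D_L=d_l,
        P_vec=p_vec,
        P=p,
        P_L=p_l,
        M_D=m_d,
        M_R=m_r,
        M_Delta=m_delta,
        R=r_tot,
        delta_L=delta_l,
        psi=psi,
        Delta=delta_cap,
        flags=flags,
    )


@dataclass(frozen=True)
class MMTParams:
    """Mueller-matrix transformation parameters b, t1 and anisotropy A."""

    b: float
    t1: float
    A: float


def mmt_params(M: MuellerMatrix | np.ndarray) -> MMTParams:
    """MMT parameters of a normalized matrix.

    Using the two central linear-diagonal elements (1-based m22, m33 of the
    MMT literature): b is their mean, t1 the anisotropy magnitude
    √((m22−m33)² + (m23+m32)²)/2, and A = 2·b·t1/(b²+t1²) the normalized
    anisotropy (0 for isotropic media, 1 for a pure linear retarder or
    diattenuator).  All three are insensitive to in-plane sample rotation.
    """
    m = _as_array(M)
    m = m / m[0, 0]
    b = (m[1, 1] + m[2, 2]) / 2.0
    t1 = np.hypot(m[1, 1] - m[2, 2], m[1, 2] + m[2, 1]) / 2.0
    denom = b * b + t1 * t1
    a = 0.0 if denom == 0 else 2.0 * b * t1 / denom
    return MMTParams(b=float(b), t1=float(t1), A=float(a))


@dataclass
class FeatureVector:
    """Named 25-element polarimetric descriptor (16 elements + 9 derived)."""

    values: dict[str, float]
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [n for n in FEATURE_NAMES if n not in self.values]
        if missing:
            raise ValueError(f"feature vector missing entries: {missing}")
        extra = [n for n in self.values if n not in FEATURE_NAMES]
        if extra:
            raise ValueError(f"unknown feature names: {extra}")
        bad = [n for n, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite feature values: {bad}")

    def __len__(self) -> int:
        return len(FEATURE_NAMES)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES])

    @classmethod
    def from_array(cls, a: np.ndarray, flags: list[str] | None = None) -> "FeatureVector":
        a = np.asarray(a, dtype=float)
        if a.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"expected {len(FEATURE_NAMES)} values, got {a.shape}")
        return cls(dict(zip(FEATURE_NAMES, a.tolist())), flags or [])


def feature_vector(M: MuellerMatrix | np.ndarray) -> FeatureVector:
    """Assemble the 25 features of a Mueller matrix.

    Element features come from the m00-normalized matrix; derived features
    from the Lu–Chipman decomposition and the MMT parameters.  Decomposition
    warnings surface as flags, never as silent NaNs.
    """
    m = _as_array(M)
    m = m / m[0, 0]
    lc = lu_chipman(m)
    mmt = mmt_params(m)
    values = {name: float(m.ravel()[i]) for i, name in enumerate(_ELEMENT_NAMES)}
    values.update(
        D=lc.D,
        P_L=lc.P_L,
        Delta=lc.Delta,
        R=lc.R,
        delta_L=lc.delta_L,
        psi=lc.psi,
        b=mmt.b,
        t1=mmt.t1,
        A=mmt.A,
    )
    clean = {k: (0.0 if not np.isfinite(v) else float(v)) for k, v in values.items()}
    flags = list(lc.flags)
    if clean != {k: float(v) for k, v in values.items()}:
        flags.append("nonfinite_replaced")
    return FeatureVector(clean, flags)
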