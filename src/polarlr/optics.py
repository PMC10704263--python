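"""Stokes–Mueller forward model and per-pixel Mueller-matrix reconstruction.

The measurement model is the standard transmission polarimeter: unpolarized
light passes a polarization state generator (PSG: linear polarizer then
quarter-wave plate), the sample (Mueller matrix ``M``), and a polarization
state analyzer (PSA: quarter-wave plate then linear polarizer).  The detected
intensity for acquisition state *k* is

    I_k = a_k^T  M  s_k

with ``s_k`` the generated Stokes vector and ``a_k`` the analyzer row.  Each
intensity is therefore linear in the 16 elements of ``M``; a sequence of >=16
well-conditioned states lets ``M`` be recovered per pixel by least squares.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
import numpy as np

__all__ = [
    "StokesVector",
    "MuellerMatrix",
    "PolState",
    "PolStateSequence",
    "IntensityStack",
    "linear_polarizer",
    "linear_retarder",
    "linear_diattenuator",
    "isotropic_depolarizer",
    "rotation_mueller",
    "psg_stokes",
    "psa_row",
    "simulate_intensities",
    "reconstruct_mueller",
    "normalize_mueller",
    "random_physical_mueller",
]

_UNPOLARIZED = np.array([1.0, 0.0, 0.0, 0.0])


# ---------------------------------------------------------------------------
# elementary Mueller matrices


def linear_polarizer(angle_deg: float) -> np.ndarray:
    """Ideal linear polarizer with transmission axis at ``angle_deg``."""
    t = np.deg2rad(angle_deg)
    c, s = np.cos(2 * t), np.sin(2 * t)
    return 0.5 * np.array(
        [
            [1, c, s, 0],
            [c, c * c, c * s, 0],
            [s, c * s, s * s, 0],
            [0, 0, 0, 0],
        ]
    )


def linear_retarder(axis_deg: float, retardance_rad: float) -> np.ndarray:
    """Ideal linear retarder, fast axis ``axis_deg``, retardance in radians."""
    t = np.deg2rad(axis_deg)
    c, s = np.cos(2 * t), np.sin(2 * t)
    cd, sd = np.cos(retardance_rad), np.sin(retardance_rad)
    return np.array(
        [
            [1, 0, 0, 0],
            [0, c * c + s * s * cd, c * s * (1 - cd), -s * sd],
            [0, c * s * (1 - cd), s * s + c * c * cd, c * sd],
            [0, s * sd, -c * sd, cd],
        ]
    )


def linear_diattenuator(axis_deg: float, diattenuation: float) -> np.ndarray:
    """Partial linear diattenuator (unit mean transmittance), D in [0, 1)."""
    if not 0.0 <= diattenuation <= 1.0:
        raise ValueError(f"diattenuation must be in [0, 1], got {diattenuation}")
    t = np.deg2rad(axis_deg)
    d_vec = diattenuation * np.array([np.cos(2 * t), np.sin(2 * t), 0.0])
    return diattenuator_from_vector(d_vec)


def diattenuator_from_vector(d_vec: np.ndarray) -> np.ndarray:
    """Diattenuator Mueller matrix from a diattenuation 3-vector."""
    d_vec = np.asarray(d_vec, dtype=float)
    d = np.linalg.norm(d_vec)
    m = np.eye(4)
    m[0, 1:] = d_vec
    m[1:, 0] = d_vec
    a = np.sqrt(max(1.0 - d * d, 0.0))
    if d > 0:
        dhat = d_vec / d
        m[1:, 1:] = a * np.eye(3) + (1.0 - a) * np.outer(dhat, dhat)
    else:
        m[1:, 1:] = np.eye(3)
    return m


def isotropic_depolarizer(depolarization: float) -> np.ndarray:
    """Isotropic depolarizer diag(1, 1-Δ, 1-Δ, 1-Δ), Δ in [0, 1]."""
    if not 0.0 <= depolarization <= 1.0:
        raise ValueError(f"depolarization must be in [0, 1], got {depolarization}")
    return np.diag([1.0, 1 - depolarization, 1 - depolarization, 1 - depolarization])


def rotation_mueller(angle_deg: float) -> np.ndarray:
    """Mueller rotation matrix for a coordinate rotation by ``angle_deg``."""
    t = np.deg2rad(angle_deg)
    c, s = np.cos(2 * t), np.sin(2 * t)
    return np.array(
        [
            [1, 0, 0, 0],
            [0, c, s, 0],
            [0, -s, c, 0],
            [0, 0, 0, 1],
        ]
    )


def random_physical_mueller(rng: np.random.Generator) -> np.ndarray:
    """Random physical Mueller matrix built as depolarizer·retarder·diattenuator.

    Products of physical factors are physical; this is the sampler used by the
    round-trip and range-containment property tests.
    """
    dep = isotropic_depolarizer(rng.uniform(0.0, 0.9))
    ret = linear_retarder(rng.uniform(0.0, 180.0), rng.uniform(0.0, np.pi))
    dia = linear_diattenuator(rng.uniform(0.0, 180.0), rng.uniform(0.0, 0.9))
    rot = rotation_mueller(rng.uniform(0.0, 180.0))
    return dep @ rot @ ret @ dia


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class StokesVector:
    """Stokes 4-vector (I, Q, U, V).

    I is total intensity, Q the horizontal−vertical linear component, U the
    45°−135° linear component, V the right−left circular component.
    """

    I: float
    Q: float
    U: float
    V: float

    _TOL = 1e-9

    def __post_init__(self) -> None:
        if self.I < -self._TOL:
            raise ValueError(f"Stokes I must be >= 0, got {self.I}")
        if self.polarized_intensity() > self.I * (1 + 1e-6) + self._TOL:
            raise ValueError(
                f"unphysical Stokes vector: Q²+U²+V² > I² ({self.as_array()})"
            )

    @classmethod
    def from_array(cls, a: np.ndarray) -> "StokesVector":
        a = np.asarray(a, dtype=float)
        return cls(*a.tolist())

    def as_array(self) -> np.ndarray:
        return np.array([self.I, self.Q, self.U, self.V])

    def polarized_intensity(self) -> float:
        return float(np.sqrt(self.Q**2 + self.U**2 + self.V**2))

    def degree_of_polarization(self) -> float:
        if self.I == 0:
            return 0.0
        return self.polarized_intensity() / self.I


@dataclass(frozen=True)
class MuellerMatrix:
    """4×4 real polarization transfer matrix, elements m00..m33 (0-based)."""

    m: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"Mueller matrix must be 4x4, got shape {m.shape}")
        object.__setattr__(self, "m", m)

    @property
    def m00(self) -> float:
        return float(self.m[0, 0])

    def normalize(self) -> "MuellerMatrix":
        return normalize_mueller(self)

    def apply(self, s: StokesVector) -> StokesVector:
        return StokesVector.from_array(self.m @ s.as_array())

    def is_physical(self, n_probe: int = 32, tol: float = 1e-6) -> bool:
        """Check that a probe set of fully polarized states maps to physical states."""
        if self.m00 <= 0:
            return False
        thetas = np.linspace(0, np.pi, n_probe, endpoint=False)
        phis = np.linspace(-np.pi / 2, np.pi / 2, 7)
        for th in thetas:
            for ph in phis:
                s_in = np.array(
                    [1.0, np.cos(2 * th) * np.cos(ph), np.sin(2 * th) * np.cos(ph), np.sin(ph)]
                )
                s_out = self.m @ s_in
                if s_out[0] < -tol:
                    return False
                if np.sum(s_out[1:] ** 2) > s_out[0] ** 2 * (1 + tol) + tol:
                    return False
        return True


def normalize_mueller(M: MuellerMatrix | np.ndarray) -> MuellerMatrix:
    """Divide all elements by m00 so the intensity scale cancels. Idempotent."""
    arr = M.m if isinstance(M, MuellerMatrix) else np.asarray(M, dtype=float)
    m00 = arr[0, 0]
    if m00 <= 0:
        raise ValueError(f"cannot normalize Mueller matrix with m00 = {m00} <= 0")
    return MuellerMatrix(arr / m00, normalized=True)


@dataclass(frozen=True)
class PolState:
    """One acquisition state: PSG polarizer/QWP and PSA QWP/polarizer angles (deg)."""

    psg_pol_angle: float
    psg_qwp_angle: float
    psa_qwp_angle: float
    psa_pol_angle: float

    def __post_init__(self) -> None:
        for name in ("psg_pol_angle", "psg_qwp_angle", "psa_qwp_angle", "psa_pol_angle"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
            object.__setattr__(self, name, float(v) % 180.0)

    def to_dict(self) -> dict:
        return {
            "psg_pol": self.psg_pol_angle,
            "psg_qwp": self.psg_qwp_angle,
            "psa_qwp": self.psa_qwp_angle,
            "psa_pol": self.psa_pol_angle,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolState":
        return cls(d["psg_pol"], d["psg_qwp"], d["psa_qwp"], d["psa_pol"])


# default acquisition protocol: 6 PSG QWP angles x 4 PSA QWP angles = 24 frames,
# both polarizers fixed at 0 deg; measured design-matrix condition number ~17.
_DEFAULT_PSG_QWP = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)
_DEFAULT_PSA_QWP = (0.0, 30.0, 60.0, 120.0)


@dataclass
class PolStateSequence:
    """Ordered acquisition protocol inducing the linear system for reconstruction."""

    states: list[PolState] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)

    @classmethod
    def default(cls) -> "PolStateSequence":
        states = [
            PolState(0.0, gq, aq, 0.0)
            for aq in _DEFAULT_PSA_QWP
            for gq in _DEFAULT_PSG_QWP
        ]
        return cls(states)

    def design_matrix(self) -> np.ndarray:
        """(n_states, 16) matrix W with I_k = W[k] @ M.ravel()."""
        rows = [
            np.outer(psa_row(s), psg_stokes(s).as_array()).ravel() for s in self.states
        ]
        return np.array(rows)

    @property
    def design_matrix_cond(self) -> float:
        return float(np.linalg.cond(self.design_matrix()))

    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.design_matrix()))

    def to_json(self) -> str:
        return json.dumps([s.to_dict() for s in self.states], indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PolStateSequence":
        return cls([PolState.from_dict(d) for d in json.loads(text)])


@dataclass
class IntensityStack:
    """Per-state intensity frames, shape (n_states, H, W), plus the manifest."""

    frames: np.ndarray
    manifest: PolStateSequence

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (n, H, W), got {self.frames.shape}")
        if self.frames.shape[0] != len(self.manifest):
            raise ValueError(
                f"frame count {self.frames.shape[0]} != manifest length {len(self.manifest)}"
            )


# ---------------------------------------------------------------------------
# forward model


def psg_stokes(state: PolState) -> StokesVector:
    """Stokes vector generated from unpolarized unit-intensity light.

    Polarizer first (half the intensity survives), then the quarter-wave
    plate; the result is always fully polarized.
    """
    s = (
        linear_retarder(state.psg_qwp_angle, np.pi / 2)
        @ linear_polarizer(state.psg_pol_angle)
        @ _UNPOLARIZED
    )
    return StokesVector.from_array(s)


def psa_row(state: PolState) -> np.ndarray:
    """Analyzer projection row: first row of polarizer·QWP on the detection side."""
    return (linear_polarizer(state.psa_pol_angle) @ linear_retarder(state.psa_qwp_angle, np.pi / 2))[0]


def simulate_intensities(
    M: MuellerMatrix | np.ndarray,
    seq: PolStateSequence,
    noise_sd: float = 0.0,
    shape: tuple[int, int] = (1, 1),
    rng: np.random.Generator | None = None,
) -> IntensityStack:
    """Simulate detected intensities I_k = a_k · M · s_k for every state.

    ``noise_sd`` is the standard deviation of additive Gaussian noise expressed
    as a fraction of the mean noiseless intensity; with ``noise_sd=0`` the map
    is exact.  A homogeneous (H, W) scene of the same matrix is produced when
    ``shape`` is given, so reconstruction can be exercised image-wise.
    """
    arr = M.m if isinstance(M, MuellerMatrix) else np.asarray(M, dtype=float)
    if arr[0, 0] <= 0:
        raise ValueError(f"non-physical Mueller matrix: m00 = {arr[0, 0]} <= 0")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    w = seq.design_matrix()
    intensities = w @ arr.ravel()  # (n_states,)
    frames = np.broadcast_to(
        intensities[:, None, None], (len(seq), *shape)
    ).copy()
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        scale = noise_sd * float(np.mean(np.abs(intensities)))
        frames += rng.normal(0.0, scale, size=frames.shape)
    return IntensityStack(frames, seq)


# ---------------------------------------------------------------------------
# reconstruction


def reconstruct_mueller(stack: IntensityStack) -> np.ndarray:
    """Per-pixel least-squares Mueller reconstruction.

    Returns an array of shape (4, 4, H, W).  The pseudo-inverse of the design
    matrix is computed once per manifest and applied to all pixels.  Pixels
    containing NaN in any frame propagate as all-NaN matrices.
    """
    seq = stack.manifest
    n = len(seq)
    if n < 16:
        raise ValueError(
            f"manifest has {n} states; at least 16 are required to determine "
            "the 16 Mueller elements"
        )
    w = seq.design_matrix()
    if np.linalg.matrix_rank(w) < 16:
        raise ValueError(
            "rank-deficient acquisition manifest: the induced design matrix has "
            f"rank {np.linalg.matrix_rank(w)} < 16; protocol "
            f"(n_states={n}) cannot determine all Mueller elements"
        )
    pinv = np.linalg.pinv(w)  # (16, n_states)
    n_states, h, wd = stack.frames.shape
    flat = stack.frames.reshape(n_states, h * wd)
    bad = np.any(np.isnan(flat), axis=0)
    flat = np.where(np.isnan(flat), 0.0, flat)
    m = pinv @ flat  # (16, H*W)
    m[:, bad] = np.nan
    return m.reshape(4, 4, h, wd)


def centroid_drift(frames: np.ndarray) -> float:
    """Max frame-to-frame drift (pixels) of the intensity centroid.

    Real stacks are assumed registered upstream; this is the cheap sanity
    check readers use to warn when that assumption looks violated.
    """
    frames = np.asarray(frames, dtype=float)
    n, h, w = frames.shape
    ys, xs = np.mgrid[0:h, 0:w]
    cents = []
    for f in frames:
        tot = np.nansum(f)
        if tot <= 0:
            cents.append((h / 2, w / 2))
            continue
        cents.append((np.nansum(ys * f) / tot, np.nansum(xs * f) / tot))
    cents_arr = np.array(cents)
    if len(cents_arr) < 2:
        return 0.0
    d = np.diff(cents_arr, axis=0)
    return float(np.max(np.hypot(d[:, 0], d[:, 1])))
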