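"""Rigid fusion of the electroanatomical-map frame with the CT frame.

The clinical merge step of map and CT is reproduced here as a documented,
standard registration: paired-landmark Kabsch initialization followed by
point-to-point ICP refinement. No scaling term — both frames are metric (mm).
``perturb_transform`` supports sensitivity studies of the distance measurement
to residual misregistration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "RegistrationResult",
    "kabsch_align",
    "icp_register",
    "apply_transform",
    "perturb_transform",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion y = R x + t (rotation 3x3, translation mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-6:
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det +1, no reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, degrees."""
        return float(np.degrees(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec())))

    # JSON interchange: 9 row-major rotation entries + 3 translation entries (mm)
    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"rotation_row_major": self.rotation.ravel().tolist(),
                       "translation_mm": self.translation.tolist()}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["rotation_row_major"]).reshape(3, 3),
                   np.asarray(d["translation_mm"]))


@dataclass(frozen=True)
class RegistrationResult:
    transform: RigidTransform
    rms_residual: float          # mm
    iterations: int
    converged: bool
    rms_history: tuple = ()      # per-iteration RMS, mm

    def __post_init__(self):
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be >= 0")


def apply_transform(T: RigidTransform, points) -> np.ndarray:
    """Map points through the rigid transform (y = R x + t)."""
    return T.apply(points)


def kabsch_align(source, target) -> RigidTransform:
    """Least-squares rigid transform (no scaling, no reflection) for paired points.

    Minimizes sum ||R s_i + t - target_i||^2 over proper rotations via SVD of the
    cross-covariance. Requires >= 3 non-collinear pairs.
    """
    s = np.asarray(source, dtype=float)
    g = np.asarray(target, dtype=float)
    if s.shape != g.shape or s.ndim != 2 or s.shape[1] != 3:
        raise ValueError("source and target must be equal-shape (n, 3) arrays")
    if len(s) < 3:
        raise ValueError("need at least 3 point pairs")
    sc, gc = s.mean(axis=0), g.mean(axis=0)
    s0, g0 = s - sc, g - gc
    # collinearity: second singular value of the centered source ~ 0
    sv = np.linalg.svd(s0, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise ValueError("source points are collinear; rotation is not determined")
    H = s0.T @ g0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = gc - R @ sc
    return RigidTransform(R, t)


def icp_register(source_cloud, target_cloud, init: RigidTransform | None = None,
                 max_iter: int = 50, tol_mm: float = 1e-6) -> RegistrationResult:
    """Point-to-point ICP: alternate nearest-neighbour pairing and Kabsch.

    RMS residual is non-increasing across iterations; stops when the RMS change
    falls below ``tol_mm`` or at ``max_iter``.
    """
    src = np.asarray(source_cloud, dtype=float)
    tgt = np.asarray(target_cloud, dtype=float)
    if src.size == 0 or tgt.size == 0:
        raise ValueError("point clouds must be non-empty")
    T = init if init is not None else RigidTransform.identity()
    tree = cKDTree(tgt)
    history = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        moved = T.apply(src)
        d, j = tree.query(moved)
        rms = float(np.sqrt(np.mean(d ** 2)))
        history.append(rms)
        T_step = kabsch_align(moved, tgt[j])
        T = T_step.compose(T)
        if len(history) >= 2 and abs(history[-2] - history[-1]) < tol_mm:
            converged = True
            break
        if rms < tol_mm:
            converged = True
            break
    d, _ = tree.query(T.apply(src))
    final_rms = float(np.sqrt(np.mean(d ** 2)))
    history.append(final_rms)
    return RegistrationResult(T, final_rms, it, converged, tuple(history))


def perturb_transform(T: RigidTransform, rotation_deg: float, translation_mm: float,
                      seed: int | np.random.Generator = 0) -> RigidTransform:
    """Compose ``T`` with a random rigid perturbation of given magnitudes.

    The perturbation is a rotation of exactly ``rotation_deg`` about a uniformly
    random axis through the origin, followed by a translation of exactly
    ``translation_mm`` in a uniformly random direction. Deterministic for a
    fixed seed. Used to emulate residual merge error between map and CT frames.
    """
    if rotation_deg < 0 or translation_mm < 0:
        raise ValueError("perturbation magnitudes must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def _unit(r):
        v = r.normal(size=3)
        return v / np.linalg.norm(v)

    R = Rotation.from_rotvec(np.radians(rotation_deg) * _unit(rng)).as_matrix() \
        if rotation_deg > 0 else np.eye(3)
    t = translation_mm * _unit(rng) if translation_mm > 0 else np.zeros(3)
    return RigidTransform(R, t).compose(T)
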