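"""Rigid motions in 3D and least-squares rigid registration.

All lengths are millimetres, all angles are degrees at the API surface
(radians internally).  Rotations are proper (det = +1); reflections are
rejected everywhere.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometry

_ORTHO_TOL = 1e-9


def _as_vec3(v) -> np.ndarray:
    a = np.asarray(v, dtype=float).reshape(3)
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite 3-vector")
    return a


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``p -> rotation @ p + translation``."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = _as_vec3(self.translation)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthogonal")
        if np.linalg.det(R) < 0:
            raise ValueError("improper rotation (reflection) rejected")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        return cls(np.eye(3), _as_vec3(t))

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float, center=None) -> "RigidTransform":
        """Rotation by ``angle_deg`` about ``axis`` through ``center``.

        Right-hand rule about the (normalised) axis; ``center`` defaults
        to the origin.
        """
        axis = _as_vec3(axis)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("zero rotation axis")
        R = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / n).as_matrix()
        if center is None:
            return cls(R, np.zeros(3))
        c = _as_vec3(center)
        return cls(R, c - R @ c)

    # -- algebra ------------------------------------------------------
    def apply(self, points) -> np.ndarray:
        """Apply the motion to one point or an (n, 3) array of points."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the motion "self after other"."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -(Rt @ self.translation))

    def is_identity(self, tol: float = 1e-12) -> bool:
        return bool(
            np.allclose(self.rotation, np.eye(3), atol=tol)
            and np.allclose(self.translation, 0.0, atol=tol)
        )

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]))


def solve_rigid(source, target) -> tuple[RigidTransform, float]:
    """Least-squares proper rigid motion mapping ``source`` onto ``target``.

    Classic SVD (Kabsch) solution of the orthogonal Procrustes problem
    with reflections excluded.  Returns the transform and the RMS
    residual in mm.

    Raises
    ------
    DegenerateGeometry
        If fewer than 3 point pairs are given or the source points are
        (numerically) collinear, so the rotation is not unique.
    """
    src = np.asarray(source, dtype=float).reshape(-1, 3)
    dst = np.asarray(target, dtype=float).reshape(-1, 3)
    if src.shape != dst.shape:
        raise ValueError("point sets must have equal shape")
    if src.shape[0] < 3:
        raise DegenerateGeometry("need at least 3 point pairs")

    c_src = src.mean(axis=0)
    c_dst = dst.mean(axis=0)
    a = src - c_src
    b = dst - c_dst

    s = np.linalg.svd(a, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometry("source points are collinear or coincident")

    H = a.T @ b
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T

    t = c_dst - R @ c_src
    transform = RigidTransform(R, t)
    resid = transform.apply(src) - dst
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return transform, rms
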