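"""Rigid 3D transforms and weighted point sets.

Conventions used throughout the package: right-handed coordinates, all
lengths in millimetres, rotations stored as 3x3 matrices.  Quaternions are
accepted at I/O boundaries only and converted on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation as _Rotation

from .errors import InvalidGeometryError, InvalidPoseError

#: Numerical tolerance for orthonormality / unit-determinant checks.
ORTHONORMAL_TOL = 1e-9


def _check_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise InvalidPoseError(f"rotation must be 3x3, got {R.shape}")
    if not np.all(np.isfinite(R)):
        raise InvalidPoseError("rotation contains non-finite entries")
    err = np.abs(R.T @ R - np.eye(3)).max()
    det = np.linalg.det(R)
    if err > ORTHONORMAL_TOL or abs(det - 1.0) > ORTHONORMAL_TOL:
        raise InvalidPoseError(
            f"matrix is not a proper rotation (orthonormality error {err:.3e}, "
            f"det {det:.12f}); use RigidTransform.from_matrix to re-project"
        )
    return R


def nearest_rotation(M: np.ndarray) -> np.ndarray:
    """Project an approximate rotation onto SO(3) (nearest in Frobenius norm)."""
    U, _, Vt = np.linalg.svd(np.asarray(M, dtype=float))
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ D @ Vt


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``p -> R p + t`` (rotation dimensionless, t in mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = _check_rotation(self.rotation)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(t)):
            raise InvalidPoseError("translation contains non-finite entries")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- constructors -------------------------------------------------------

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, M, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Build from an approximate rotation, re-orthonormalising on drift.

        Matrices already within ``ORTHONORMAL_TOL`` are used verbatim; others
        are projected to the nearest proper rotation.
        """
        M = np.asarray(M, dtype=float)
        if M.shape != (3, 3) or not np.all(np.isfinite(M)):
            raise InvalidPoseError("expected a finite 3x3 matrix")
        err = np.abs(M.T @ M - np.eye(3)).max()
        if err > ORTHONORMAL_TOL or np.linalg.det(M) <= 0:
            M = nearest_rotation(M)
        return cls(M, np.asarray(translation, dtype=float))

    @classmethod
    def from_quaternion(cls, q_xyzw, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """I/O-boundary constructor; quaternion in scalar-last (x, y, z, w) order."""
        q = np.asarray(q_xyzw, dtype=float).reshape(4)
        n = np.linalg.norm(q)
        if not np.isfinite(n) or n == 0:
            raise InvalidPoseError("quaternion must be finite and nonzero")
        return cls(_Rotation.from_quat(q / n).as_matrix(), translation)

    @classmethod
    def from_euler_deg(cls, rx, ry, rz, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Intrinsic x-y-z Euler angles in degrees (convenience for configs)."""
        R = _Rotation.from_euler("xyz", [rx, ry, rz], degrees=True).as_matrix()
        return cls.from_matrix(R, translation)

    # -- algebra ------------------------------------------------------------

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array or a single 3-vector."""
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        if p.shape[-1] != 3:
            raise InvalidGeometryError(f"points must be (N, 3), got {p.shape}")
        if not np.all(np.isfinite(p)):
            raise InvalidGeometryError("points contain non-finite coordinates")
        out = p @ self.rotation.T + self.translation
        return out[0] if single else out

    def compose(self, inner: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ inner`` (``inner`` applied first)."""
        return RigidTransform.from_matrix(
            self.rotation @ inner.rotation,
            self.rotation @ inner.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def is_close(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=atol)
            and np.allclose(self.translation, other.translation, atol=atol)
        )

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation_mm": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        if "quaternion_xyzw" in d:
            return cls.from_quaternion(d["quaternion_xyzw"], d.get("translation_mm", (0, 0, 0)))
        try:
            return cls.from_matrix(d["rotation"], d.get("translation_mm", (0, 0, 0)))
        except KeyError as e:
            raise InvalidPoseError(f"transform dict missing key {e}") from e


@dataclass(frozen=True)
class PointSet:
    """N points in mm with optional non-negative per-point weights."""

    points: np.ndarray
    weights: np.ndarray | None = field(default=None)

    def __post_init__(self):
        p = np.atleast_2d(np.asarray(self.points, dtype=float))
        if p.shape[-1] != 3:
            raise InvalidGeometryError(f"points must be (N, 3), got {p.shape}")
        if not np.all(np.isfinite(p)):
            raise InvalidGeometryError("points contain non-finite coordinates")
        object.__setattr__(self, "points", p)
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float).reshape(-1)
            if w.shape[0] != p.shape[0]:
                raise InvalidGeometryError("weights length must match point count")
            if np.any(w < 0) or not np.all(np.isfinite(w)) or w.sum() <= 0:
                raise InvalidGeometryError("weights must be finite, >= 0, with positive sum")
            object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.points.shape[0]


def apply_transform(T: RigidTransform, P: PointSet) -> PointSet:
    """Transform every point of ``P`` by ``T``; weights carried through."""
    if len(P) == 0:
        raise InvalidGeometryError("cannot transform an empty point set")
    return PointSet(T.apply(P.points), P.weights)


def compose(T2: RigidTransform, T1: RigidTransform) -> RigidTransform:
    """Composite transform applying ``T1`` first, then ``T2``."""
    return T2.compose(T1)


def invert(T: RigidTransform) -> RigidTransform:
    return T.inverse()


def pose_difference(
    T_est: RigidTransform, T_true: RigidTransform, reference_point=(0.0, 0.0, 0.0)
) -> tuple[float, float]:
    """(translation error at a reference point [mm], rotation error [deg]).

    The translation component of a pose error depends on the origin; measuring
    displacement at a stated reference point (typically the model centroid)
    makes the number meaningful.
    """
    delta = T_est.compose(T_true.inverse())
    ref = np.asarray(reference_point, dtype=float)
    trans_err = float(np.linalg.norm(T_est.apply(ref) - T_true.apply(ref)))
    return trans_err, delta.rotation_angle_deg()
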