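"""Pinhole stereo model: projection, two-view triangulation, patch reconstruction.

Image convention: origin at the top-left, u rightward, v downward, pixel
centres at integer coordinates.  No lens distortion model — correspondences
are assumed pre-undistorted; a distortion hook belongs at the ingest boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cloud import LabeledPointCloud
from .errors import (
    BehindCameraError,
    DegenerateGeometryError,
    EmptyReconstructionError,
    InvalidGeometryError,
)
from .transforms import RigidTransform

#: Rays closer to parallel than this (radians) are treated as degenerate.
PARALLEL_TOL_RAD = 1e-8


@dataclass(frozen=True)
class PinholeCamera:
    """Intrinsics in pixels plus a world→camera rigid pose."""

    fx: float
    fy: float
    cx: float
    cy: float
    image_size: tuple[int, int]  # (width, height)
    pose: RigidTransform = field(default_factory=RigidTransform.identity)

    def __post_init__(self):
        w, h = self.image_size
        if self.fx <= 0 or self.fy <= 0:
            raise InvalidGeometryError("focal lengths must be positive")
        if not (0 <= self.cx < w and 0 <= self.cy < h):
            raise InvalidGeometryError("principal point must lie inside the image")

    @property
    def center_world(self) -> np.ndarray:
        """Camera centre in world coordinates."""
        return self.pose.inverse().translation

    def ray_world(self, pixel) -> tuple[np.ndarray, np.ndarray]:
        """(origin, unit direction) of the back-projected ray in world frame."""
        u, v = float(pixel[0]), float(pixel[1])
        d_cam = np.array([(u - self.cx) / self.fx, (v - self.cy) / self.fy, 1.0])
        d_world = self.pose.rotation.T @ d_cam
        return self.center_world, d_world / np.linalg.norm(d_world)

    def with_pose(self, pose: RigidTransform) -> "PinholeCamera":
        return PinholeCamera(self.fx, self.fy, self.cx, self.cy, self.image_size, pose)

    def in_bounds(self, uv: np.ndarray) -> np.ndarray:
        uv = np.atleast_2d(uv)
        w, h = self.image_size
        return (uv[:, 0] >= 0) & (uv[:, 0] <= w - 1) & (uv[:, 1] >= 0) & (uv[:, 1] <= h - 1)

    def to_dict(self) -> dict:
        return {
            "fx": self.fx, "fy": self.fy, "cx": self.cx, "cy": self.cy,
            "image_size": list(self.image_size), "pose": self.pose.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PinholeCamera":
        pose = RigidTransform.from_dict(d["pose"]) if "pose" in d else RigidTransform.identity()
        return cls(d["fx"], d["fy"], d["cx"], d["cy"], tuple(d["image_size"]), pose)


@dataclass(frozen=True)
class StereoRig:
    left: PinholeCamera
    right: PinholeCamera

    def __post_init__(self):
        if self.baseline_mm == 0:
            raise InvalidGeometryError("stereo cameras must have nonzero baseline")

    @property
    def baseline_mm(self) -> float:
        return float(np.linalg.norm(self.left.center_world - self.right.center_world))

    def transformed(self, world_to_rig: RigidTransform) -> "StereoRig":
        """Rig placed in the world: camera poses become world→camera."""
        return StereoRig(
            self.left.with_pose(self.left.pose.compose(world_to_rig)),
            self.right.with_pose(self.right.pose.compose(world_to_rig)),
        )

    def to_dict(self) -> dict:
        return {"left": self.left.to_dict(), "right": self.right.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "StereoRig":
        return cls(PinholeCamera.from_dict(d["left"]), PinholeCamera.from_dict(d["right"]))


@dataclass(frozen=True)
class StereoCorrespondence:
    """A matched pixel pair with its source-surface class label (0 = liver)."""

    pixel_left: tuple[float, float]
    pixel_right: tuple[float, float]
    label: int = 0


def project(cam: PinholeCamera, p_world) -> tuple[float, float]:
    """World point → (u, v) pixels; raises BehindCameraError for z <= 0."""
    p = cam.pose.apply(np.asarray(p_world, dtype=float))
    if p[2] <= 0:
        raise BehindCameraError(f"point has camera-frame depth {p[2]:.3f} mm")
    return (cam.fx * p[0] / p[2] + cam.cx, cam.fy * p[1] / p[2] + cam.cy)


def project_many(cam: PinholeCamera, points: np.ndarray):
    """Vectorised projection. Returns (uv (N,2), in_front mask)."""
    p = cam.pose.apply(np.atleast_2d(np.asarray(points, dtype=float)))
    z = p[:, 2]
    in_front = z > 0
    zsafe = np.where(in_front, z, 1.0)
    uv = np.column_stack([cam.fx * p[:, 0] / zsafe + cam.cx, cam.fy * p[:, 1] / zsafe + cam.cy])
    return uv, in_front


def triangulate(rig: StereoRig, c: StereoCorrespondence) -> np.ndarray:
    """Least-squares two-ray intersection (midpoint of the common perpendicular).

    Minimises the summed squared distance to the two back-projected rays.
    """
    o1, d1 = rig.left.ray_world(c.pixel_left)
    o2, d2 = rig.right.ray_world(c.pixel_right)
    sin_angle = np.linalg.norm(np.cross(d1, d2))
    if sin_angle < PARALLEL_TOL_RAD:
        raise DegenerateGeometryError(
            f"back-projected rays are parallel within {PARALLEL_TOL_RAD} rad"
        )
    A = np.zeros((3, 3))
    b = np.zeros(3)
    for o, d in ((o1, d1), (o2, d2)):
        P = np.eye(3) - np.outer(d, d)
        A += P
        b += P @ o
    return np.linalg.solve(A, b)


def triangulation_residual_mm(rig: StereoRig, c: StereoCorrespondence, point: np.ndarray) -> float:
    """RMS distance from a 3D point to the two correspondence rays."""
    res = []
    for o, d in (rig.left.ray_world(c.pixel_left), rig.right.ray_world(c.pixel_right)):
        diff = point - o
        res.append(np.linalg.norm(diff - (diff @ d) * d))
    return float(np.sqrt(np.mean(np.square(res))))


def reconstruct_patch(
    rig: StereoRig, correspondences, patch_id: int = 0
) -> tuple[LabeledPointCloud, int]:
    """Triangulate every valid correspondence into a labelled cloud.

    Degenerate correspondences are dropped and counted; returns
    (cloud, n_dropped). Raises EmptyReconstructionError when nothing survives.
    """
    correspondences = list(correspondences)
    if not correspondences:
        raise EmptyReconstructionError("no correspondences supplied")
    pts, labels, dropped = [], [], 0
    for c in correspondences:
        try:
            pts.append(triangulate(rig, c))
            labels.append(c.label)
        except DegenerateGeometryError:
            dropped += 1
    if not pts:
        raise EmptyReconstructionError(
            f"all {len(correspondences)} correspondences were degenerate"
        )
    cloud = LabeledPointCloud(
        np.array(pts),
        np.array(labels, dtype=np.int64),
        np.full(len(pts), patch_id, dtype=np.int64),
    )
    return cloud, dropped


def default_rig(
    fx: float = 1000.0,
    fy: float = 1000.0,
    image_size: tuple[int, int] = (1920, 1080),
    baseline_mm: float = 4.0,
    vergence_deg: float = 1.0,
) -> StereoRig:
    """Plausible 3D-laparoscope-like rig (invented defaults, not calibrated).

    Cameras straddle the rig origin along x, each toed in by half the
    vergence angle so their optical axes cross in front of the rig.
    """
    w, h = image_size
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    half = baseline_mm / 2.0
    poses = []
    for sign in (+1.0, -1.0):  # +1 → left camera at x = -half, toed in toward +x
        R = RigidTransform.from_euler_deg(0.0, -sign * vergence_deg / 2.0, 0.0).rotation
        center = np.array([-sign * half, 0.0, 0.0])
        poses.append(RigidTransform(R, -R @ center))
    left = PinholeCamera(fx, fy, cx, cy, image_size, poses[0])
    right = PinholeCamera(fx, fy, cx, cy, image_size, poses[1])
    return StereoRig(left, right)
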