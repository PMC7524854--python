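"""Synthetic surgical scenes: liver-like meshes, distractor sheets, landmarks,
ground-truth poses and simulated stereo observations.

Everything is driven by explicit integer seeds; regenerating with the same
seed and parameters is bit-identical. Units are mm throughout. The liver mesh
lives in *model* space; ``true_pose`` maps model space to patient space, and
distractor surfaces are defined directly in patient space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cloud import LIVER_LABEL, LabeledPointCloud
from .errors import EmptyObservationError, GenerationError, InvalidGeometryError
from .mesh import TriangleMesh, icosphere, make_sheet
from .stereo import StereoCorrespondence, StereoRig, project_many, reconstruct_patch
from .transforms import RigidTransform

#: Default liver envelope semi-axes (mm): ~250 x 150 x 100 bounding box.
DEFAULT_SEMI_AXES = (125.0, 75.0, 50.0)


def make_liver_mesh(
    seed: int,
    n_bumps: int = 12,
    bump_amp_mm: float = 8.0,
    subdivisions: int = 4,
    semi_axes: tuple[float, float, float] = DEFAULT_SEMI_AXES,
    bump_width_rad: float = 0.35,
) -> TriangleMesh:
    """Deterministic lobulated ellipsoid.

    An icosphere scaled to ``semi_axes`` and deformed by ``n_bumps`` smooth
    outward radial Gaussian bumps at seeded random directions. Bump amplitude
    controls surface feature richness; amplitude 0 gives the pure ellipsoid.
    """
    if n_bumps < 0 or bump_amp_mm < 0:
        raise GenerationError("n_bumps and bump_amp_mm must be non-negative")
    sphere = icosphere(subdivisions)
    if sphere.n_faces < 500:
        raise GenerationError("subdivisions too low: need >= 500 triangles")
    unit = sphere.vertices
    S = np.asarray(semi_axes, dtype=float)
    verts = unit * S
    if n_bumps > 0 and bump_amp_mm > 0:
        rng = np.random.default_rng(seed)
        dirs = rng.normal(size=(n_bumps, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        angles = np.arccos(np.clip(unit @ dirs.T, -1.0, 1.0))  # (V, n_bumps)
        disp = (bump_amp_mm * np.exp(-((angles / bump_width_rad) ** 2))).sum(axis=1)
        # outward radial displacement keeps the surface star-shaped, hence
        # intersection-free, unless the realised stacking gets extreme
        if disp.max() > min(semi_axes):
            raise GenerationError(
                f"realised bump stacking {disp.max():.1f} mm exceeds the smallest "
                f"semi-axis {min(semi_axes):.1f} mm; reduce n_bumps or bump_amp_mm"
            )
        radial = verts / np.linalg.norm(verts, axis=1, keepdims=True)
        verts = verts + disp[:, None] * radial
    return TriangleMesh(verts, sphere.faces)


@dataclass(frozen=True)
class DistractorSpec:
    """A smooth sheet hovering above the liver — the diaphragm stand-in."""

    clearance_mm: float = 5.0
    extent_scale: float = 1.2
    sag_mm: float = 3.0
    label: int = 1
    n_grid: int = 16


@dataclass(frozen=True)
class SyntheticScene:
    liver_mesh: TriangleMesh  # model space
    distractor_meshes: tuple  # ((TriangleMesh, label), ...) in patient space
    landmarks: dict  # name -> (3,) model-space point on the liver surface
    true_pose: RigidTransform  # model -> patient
    seed: int = 0

    def __post_init__(self):
        if not self.liver_mesh.is_watertight:
            raise InvalidGeometryError("liver mesh must be watertight")
        if self.liver_mesh.n_faces < 500:
            raise InvalidGeometryError("liver mesh must have >= 500 triangles")
        if self.landmarks:
            pts = np.array(list(self.landmarks.values()), dtype=float)
            d = self.liver_mesh.distance_to_points(pts)
            if d.max() > 1e-6:
                raise InvalidGeometryError(
                    f"landmark off the liver surface by {d.max():.3e} mm"
                )
        object.__setattr__(self, "distractor_meshes", tuple(self.distractor_meshes))

    def patient_liver_mesh(self) -> TriangleMesh:
        return self.liver_mesh.transformed(self.true_pose)

    def patient_landmarks(self) -> dict:
        return {k: self.true_pose.apply(v) for k, v in self.landmarks.items()}

    def all_patient_meshes(self):
        """[(mesh, label), ...] in patient space, liver first with label 0."""
        return [(self.patient_liver_mesh(), LIVER_LABEL), *self.distractor_meshes]


def _pick_landmarks(mesh: TriangleMesh, n: int, min_separation_mm: float = 25.0) -> dict:
    """Greedy selection of well-separated high-curvature vertices.

    Mirrors the use of ridge/notch anatomy (margins, umbilical notch) as
    landmarks: the angle-deficit curvature proxy peaks on bump ridges.
    """
    deficit = mesh.angle_deficit()
    order = np.argsort(-deficit)  # most convex first
    chosen: list[int] = []
    for idx in order:
        if len(chosen) == n:
            break
        p = mesh.vertices[idx]
        if all(np.linalg.norm(p - mesh.vertices[j]) >= min_separation_mm for j in chosen):
            chosen.append(int(idx))
    if len(chosen) < n:  # relax separation rather than fail
        for idx in order:
            if len(chosen) == n:
                break
            if int(idx) not in chosen:
                chosen.append(int(idx))
    return {f"lm_{i + 1:02d}": mesh.vertices[j].copy() for i, j in enumerate(chosen)}


def make_scene(
    seed: int,
    distractor_spec: DistractorSpec | None = None,
    n_landmarks: int = 4,
    true_pose: RigidTransform | None = None,
    **mesh_kwargs,
) -> SyntheticScene:
    """Build a full scene with known ground truth.

    ``n_landmarks >= 3`` (the TRE protocol needs at least three landmarks).
    The distractor sheet, if requested, is positioned so its minimum distance
    to the patient-space liver surface equals ``clearance_mm``.
    """
    if n_landmarks < 3:
        raise InvalidGeometryError("need at least 3 landmarks")
    true_pose = true_pose or RigidTransform.identity()
    liver = make_liver_mesh(seed, **mesh_kwargs)
    landmarks = _pick_landmarks(liver, n_landmarks)
    distractors = []
    if distractor_spec is not None:
        patient_liver = liver.transformed(true_pose)
        lo, hi = patient_liver.vertices.min(axis=0), patient_liver.vertices.max(axis=0)
        size = (hi - lo) * distractor_spec.extent_scale
        center = np.array([
            (lo[0] + hi[0]) / 2, (lo[1] + hi[1]) / 2,
            hi[2] + distractor_spec.clearance_mm + distractor_spec.sag_mm,
        ])
        sheet = make_sheet(
            center, size[0], size[1],
            n_x=distractor_spec.n_grid, n_y=distractor_spec.n_grid,
            sag_mm=distractor_spec.sag_mm,
        )
        # shift vertically until min sheet-vertex -> liver-surface distance equals
        # the clearance; a couple of fixed-point steps suffice since the closest
        # approach is near-vertical once the sheet is above the liver
        for _ in range(4):
            gap = patient_liver.distance_to_points(sheet.vertices).min()
            shift = distractor_spec.clearance_mm - gap
            if abs(shift) < 0.01:
                break
            sheet = TriangleMesh(
                sheet.vertices + np.array([0.0, 0.0, shift]), sheet.faces
            )
        distractors.append((sheet, int(distractor_spec.label)))
    return SyntheticScene(liver, tuple(distractors), landmarks, true_pose, seed)


@dataclass(frozen=True)
class Observation:
    """Simulated stereo capture of a scene from one viewpoint."""

    rig: StereoRig
    camera_pose: RigidTransform  # patient/world -> rig frame
    correspondences: tuple
    noise_sd_px: float
    visible_fraction: float  # fraction of sampled liver candidates visible
    true_points: np.ndarray = field(repr=False)  # (N, 3) patient space, pre-noise
    true_labels: np.ndarray = field(repr=False)

    def posed_rig(self) -> StereoRig:
        return self.rig.transformed(self.camera_pose)

    def reconstruct(self, patch_id: int = 0) -> tuple[LabeledPointCloud, int]:
        """Triangulate the correspondences back into a patient-space cloud."""
        return reconstruct_patch(self.posed_rig(), self.correspondences, patch_id)


def look_at_pose(eye, target, up=(0.0, 1.0, 0.0)) -> RigidTransform:
    """World→camera pose for a camera at ``eye`` looking at ``target``.

    Camera convention: z forward, x right, y down; ``up`` is only a hint for
    roll and must not be parallel to the view direction.
    """
    eye = np.asarray(eye, dtype=float)
    z = np.asarray(target, dtype=float) - eye
    nz = np.linalg.norm(z)
    if nz == 0:
        raise InvalidGeometryError("eye and target coincide")
    z /= nz
    up = np.asarray(up, dtype=float)
    x = np.cross(up, z)
    if np.linalg.norm(x) < 1e-12:
        x = np.cross(np.array([1.0, 0.0, 0.0]), z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.vstack([x, y, z])
    return RigidTransform(R, -R @ eye)


def observe(
    scene: SyntheticScene,
    rig: StereoRig,
    camera_pose: RigidTransform,
    n_points: int = 2000,
    noise_sd_px: float = 0.0,
    seed: int = 0,
    oversample: int = 4,
) -> Observation:
    """Sample visible surface points and image them through both cameras.

    Candidate points are drawn uniformly by area over the liver and all
    distractors; a candidate survives if its face is front-facing to both
    cameras, unoccluded along both view rays, and lands inside both images.
    Surviving candidates are subsampled to ``n_points`` (all kept if fewer),
    so sampling stays proportional to *visible* area. Gaussian pixel noise of
    ``noise_sd_px`` is then added independently per coordinate.
    """
    if n_points < 1:
        raise InvalidGeometryError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    posed = rig.transformed(camera_pose)
    meshes = scene.all_patient_meshes()
    areas = np.array([m.area for m, _ in meshes])
    n_cand = max(oversample * n_points, 1000)
    counts = rng.multinomial(n_cand, areas / areas.sum())

    pts_list, lab_list, nrm_list = [], [], []
    for (m, label), k in zip(meshes, counts):
        if k == 0:
            continue
        p, fi = m.sample_surface_with_faces(k, rng)
        pts_list.append(p)
        lab_list.append(np.full(k, label, dtype=np.int64))
        nrm_list.append(m.face_normals()[fi])
    pts = np.concatenate(pts_list)
    labels = np.concatenate(lab_list)
    normals = np.concatenate(nrm_list)

    visible = np.ones(len(pts), dtype=bool)
    for cam in (posed.left, posed.right):
        center = cam.center_world
        view = center - pts
        visible &= np.einsum("ij,ij->i", normals, view) > 0  # front-facing
        uv, in_front = project_many(cam, pts)
        visible &= in_front & cam.in_bounds(uv)
        # occlusion: nearest hit along the camera->point ray must be the point
        idx = np.flatnonzero(visible)
        if idx.size:
            dirs = pts[idx] - center
            t_near = np.full(idx.size, np.inf)
            for m, _ in meshes:
                t, _f = m.ray_first_hit(np.broadcast_to(center, (idx.size, 3)), dirs)
                t_near = np.minimum(t_near, t)
            visible[idx] &= t_near > 1.0 - 1e-4
    if not visible.any():
        raise EmptyObservationError("no surface point is visible from both cameras")

    liver_cand = labels == LIVER_LABEL
    vis_frac = (
        float(np.mean(visible[liver_cand])) if liver_cand.any() else 0.0
    )

    idx = np.flatnonzero(visible)
    if idx.size > n_points:
        idx = rng.choice(idx, size=n_points, replace=False)
    idx = np.sort(idx)
    sel_pts, sel_labels = pts[idx], labels[idx]

    uvl, _ = project_many(posed.left, sel_pts)
    uvr, _ = project_many(posed.right, sel_pts)
    if noise_sd_px > 0:
        uvl = uvl + rng.normal(scale=noise_sd_px, size=uvl.shape)
        uvr = uvr + rng.normal(scale=noise_sd_px, size=uvr.shape)
    keep = posed.left.in_bounds(uvl) & posed.right.in_bounds(uvr)
    corrs = tuple(
        StereoCorrespondence((float(l[0]), float(l[1])), (float(r[0]), float(r[1])), int(lab))
        for l, r, lab in zip(uvl[keep], uvr[keep], sel_labels[keep])
    )
    if not corrs:
        raise EmptyObservationError("all imaged points fell outside the sensors")
    return Observation(
        rig, camera_pose, corrs, noise_sd_px, vis_frac,
        sel_pts[keep].copy(), sel_labels[keep].copy(),
    )
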