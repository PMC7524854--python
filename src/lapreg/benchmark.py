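"""Packaged distractor-scene benchmark: oracle gating vs. passthrough.

Reproduces, in silico, the phase-one failure mode — a surface reconstructor
that cannot tell liver from diaphragm feeds ICP distractor points and
degrades the registration — and the phase-two fix of segmenting the liver
surface first. One trial runs the identical scene/observation/initialisation
through both gate variants and reports ground-truth pose errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cloud import LIVER_LABEL, LabeledPointCloud
from .errors import RegistrationFailureError
from .gate import gate_passthrough, gate_points
from .icp import ICPParams, icp_register
from .scene import DistractorSpec, look_at_pose, make_scene, observe
from .stereo import default_rig
from .transforms import RigidTransform, pose_difference

#: Benchmark ICP settings: smaller model sample for speed, failure threshold
#: at the package default 20 mm.
BENCH_ICP = ICPParams(model_sample_count=6000, max_iterations=60)


@dataclass(frozen=True)
class GatingTrial:
    seed: int
    gated_error_mm: float
    gated_error_deg: float
    gated_failed: bool
    passthrough_error_mm: float
    passthrough_error_deg: float
    passthrough_failed: bool
    distractor_fraction: float


def _rebalance(cloud: LabeledPointCloud, distractor_fraction: float,
               rng: np.random.Generator) -> LabeledPointCloud:
    """Subsample so the distractor share equals ``distractor_fraction``."""
    liver_idx = np.flatnonzero(cloud.labels == LIVER_LABEL)
    distr_idx = np.flatnonzero(cloud.labels != LIVER_LABEL)
    if liver_idx.size == 0 or distr_idx.size == 0:
        return cloud
    # largest achievable subsets at the exact ratio
    n_liver = min(liver_idx.size,
                  int(distr_idx.size * (1 - distractor_fraction) / distractor_fraction))
    n_distr = min(distr_idx.size,
                  int(n_liver * distractor_fraction / (1 - distractor_fraction)))
    keep = np.concatenate([
        rng.choice(liver_idx, size=max(1, n_liver), replace=False),
        rng.choice(distr_idx, size=max(1, n_distr), replace=False),
    ])
    return cloud.select(np.sort(keep))


def run_gating_trial(
    seed: int,
    clearance_mm: float = 5.0,
    distractor_fraction: float = 0.4,
    noise_sd_px: float = 0.5,
    n_points: int = 1500,
    init_offset_mm: float = 15.0,
    init_offset_deg: float = 8.0,
    params: ICPParams = BENCH_ICP,
) -> GatingTrial:
    """One seeded A/B trial on the diaphragm-sheet scene.

    Both arms share the scene, the observation and the initial pose; the only
    difference is whether distractor points are gated out before ICP.
    """
    rng = np.random.default_rng(seed)
    scene = make_scene(
        seed,
        distractor_spec=DistractorSpec(clearance_mm=clearance_mm),
        n_landmarks=4,
        subdivisions=3,
    )
    rig = default_rig()
    az = rng.uniform(-0.5, 0.5)
    eye = np.array([np.sin(az), -np.cos(az), 0.0]) * 320.0
    pose = look_at_pose(eye, (0.0, 0.0, 0.0), up=(0.0, 0.0, 1.0))
    obs = observe(scene, rig, pose, n_points=n_points, noise_sd_px=noise_sd_px,
                  seed=seed)
    cloud, _dropped = obs.reconstruct()
    cloud = _rebalance(cloud, distractor_fraction, rng)

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    from scipy.spatial.transform import Rotation as _R

    perturb = RigidTransform(
        _R.from_rotvec(np.radians(init_offset_deg) * axis).as_matrix(),
        rng.normal(size=3) / np.sqrt(3) * init_offset_mm,
    )
    init = perturb.compose(scene.true_pose)

    centroid = scene.liver_mesh.vertices.mean(axis=0)
    out = {}
    for arm, gated in (("gated", gate_points(cloud, 0.0)),
                       ("passthrough", gate_passthrough(cloud))):
        failed = False
        try:
            res = icp_register(gated, scene.liver_mesh, init, params, seed=seed)
        except RegistrationFailureError as e:
            failed = True
            res = e.result
        t_err, r_err = pose_difference(res.transform, scene.true_pose, centroid)
        out[arm] = (t_err, r_err, failed)
    frac = float(np.mean(cloud.labels != LIVER_LABEL))
    return GatingTrial(seed, *out["gated"], *out["passthrough"], frac)


def run_gating_benchmark(n_seeds: int = 20, base_seed: int = 0, **kwargs) -> dict:
    """Run ``n_seeds`` paired trials and summarise the contrast."""
    trials = [run_gating_trial(base_seed + i, **kwargs) for i in range(n_seeds)]
    gated = np.array([t.gated_error_mm for t in trials])
    passth = np.array([t.passthrough_error_mm for t in trials])
    return {
        "n_seeds": n_seeds,
        "median_gated_error_mm": float(np.median(gated)),
        "median_passthrough_error_mm": float(np.median(passth)),
        "mean_gated_error_mm": float(np.mean(gated)),
        "mean_passthrough_error_mm": float(np.mean(passth)),
        "n_gated_failures": int(sum(t.gated_failed for t in trials)),
        "n_passthrough_failures": int(sum(t.passthrough_failed for t in trials)),
        "mean_distractor_fraction": float(np.mean([t.distractor_fraction for t in trials])),
        "trials": [t.__dict__ for t in trials],
    }
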