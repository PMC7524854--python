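"""Landmark-based target registration error (TRE).

Per-frame Euclidean distances between registered-model landmarks and their
patient-space counterparts, summarised as a root-mean-square in mm. Landmark
identification in 2D images is a human act outside this package; inputs are
already-identified 3D positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyInputError, SchemaError
from .transforms import RigidTransform


@dataclass(frozen=True)
class FrameLandmarks:
    """Patient-space landmark observations for one video frame."""

    frame_id: int
    points: dict  # name -> (3,) mm

    def __post_init__(self):
        if not self.points:
            raise SchemaError(f"frame {self.frame_id} has no landmarks")


@dataclass(frozen=True)
class TREReport:
    per_frame_errors: tuple  # ((frame_id, name, distance_mm), ...)
    tre_mm: float
    n_frames: int
    n_landmarks: int

    def to_dict(self) -> dict:
        return {
            "tre_mm": self.tre_mm,
            "tre_mm_rounded": round(self.tre_mm, 1),
            "n_frames": self.n_frames,
            "n_landmarks": self.n_landmarks,
            "per_frame_errors": [
                {"frame_id": f, "name": n, "distance_mm": d}
                for f, n, d in self.per_frame_errors
            ],
        }


def landmark_errors(
    registration: RigidTransform,
    model_landmarks: dict,
    patient_frames: list,
) -> list:
    """[(frame_id, name, distance_mm), ...] across all frames.

    For each frame and landmark, the Euclidean distance between the
    registered model landmark and the patient-observed position.
    """
    if not patient_frames:
        raise EmptyInputError("no frames supplied")
    registered = {k: registration.apply(np.asarray(v, float)) for k, v in model_landmarks.items()}
    out = []
    for frame in patient_frames:
        for name, p in frame.points.items():
            if name not in registered:
                raise SchemaError(
                    f"frame {frame.frame_id}: landmark {name!r} not in the model set"
                )
            d = float(np.linalg.norm(registered[name] - np.asarray(p, float)))
            out.append((frame.frame_id, name, d))
    return out


def tre_rms(distances) -> float:
    """Root of the arithmetic mean of the squared distance errors."""
    d = np.asarray(list(distances), dtype=float)
    if d.size == 0:
        raise EmptyInputError("no distances supplied")
    if np.any(d < 0) or not np.all(np.isfinite(d)):
        raise SchemaError("distances must be finite and non-negative")
    return float(np.sqrt(np.mean(d * d)))


def evaluate_tre(
    registration: RigidTransform, model_landmarks: dict, patient_frames: list
) -> TREReport:
    errors = landmark_errors(registration, model_landmarks, patient_frames)
    names = {name for _, name, _ in errors}
    frames = {fid for fid, _, _ in errors}
    return TREReport(
        tuple(errors), tre_rms([d for _, _, d in errors]), len(frames), len(names)
    )
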