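"""Labelled point clouds — the reconstructed-surface currency of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidGeometryError

#: Class label for liver-surface points; anything >= 1 is a distractor class.
LIVER_LABEL = 0


@dataclass(frozen=True)
class LabeledPointCloud:
    """N points (mm) each tagged with a surface class and a source patch id."""

    points: np.ndarray
    labels: np.ndarray
    source_patch_id: np.ndarray | None = None

    def __post_init__(self):
        p = np.asarray(self.points, dtype=float).reshape(-1, 3)
        lab = np.asarray(self.labels, dtype=np.int64).reshape(-1)
        if p.shape[0] != lab.shape[0]:
            raise InvalidGeometryError("points and labels must have the same length")
        if p.size and not np.all(np.isfinite(p)):
            raise InvalidGeometryError("points contain non-finite coordinates")
        if lab.size and lab.min() < 0:
            raise InvalidGeometryError("labels must be non-negative")
        pid = self.source_patch_id
        if pid is None:
            pid = np.zeros(p.shape[0], dtype=np.int64)
        else:
            pid = np.asarray(pid, dtype=np.int64).reshape(-1)
            if pid.shape[0] != p.shape[0]:
                raise InvalidGeometryError("source_patch_id length mismatch")
        object.__setattr__(self, "points", p)
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "source_patch_id", pid)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def liver_fraction(self) -> float:
        if len(self) == 0:
            return float("nan")
        return float(np.mean(self.labels == LIVER_LABEL))

    def select(self, mask: np.ndarray) -> "LabeledPointCloud":
        return LabeledPointCloud(
            self.points[mask], self.labels[mask], self.source_patch_id[mask]
        )

    @staticmethod
    def concatenate(clouds) -> "LabeledPointCloud":
        clouds = list(clouds)
        if not clouds:
            return LabeledPointCloud(np.empty((0, 3)), np.empty(0, dtype=np.int64))
        return LabeledPointCloud(
            np.concatenate([c.points for c in clouds]),
            np.concatenate([c.labels for c in clouds]),
            np.concatenate([c.source_patch_id for c in clouds]),
        )
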