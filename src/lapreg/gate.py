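"""Segmentation gate: keep liver-labelled points before registration.

Stand-in for a learned liver-surface classifier. The gate is an oracle on
simulator labels with a configurable symmetric error rate; substitute any
real classifier by producing a LabeledPointCloud with its predicted labels
and running the oracle gate at error_rate 0.
"""

from __future__ import annotations

import numpy as np

from .cloud import LIVER_LABEL, LabeledPointCloud
from .errors import InvalidGeometryError


def gate_points(
    cloud: LabeledPointCloud, error_rate: float = 0.0, seed: int = 0
) -> LabeledPointCloud:
    """Keep each point iff (is liver) XOR (independent Bernoulli(error_rate) flip).

    ``error_rate`` 0 reproduces the perfect-segmentation case: exactly the
    liver-labelled subset, in input order. The gate never fabricates points.
    """
    if not (0.0 <= error_rate < 1.0):
        raise InvalidGeometryError("error_rate must be in [0, 1)")
    if len(cloud) == 0:
        return cloud
    is_liver = cloud.labels == LIVER_LABEL
    if error_rate == 0.0:
        return cloud.select(is_liver)
    rng = np.random.default_rng(seed)
    flip = rng.random(len(cloud)) < error_rate
    return cloud.select(is_liver ^ flip)


def gate_passthrough(cloud: LabeledPointCloud) -> LabeledPointCloud:
    """Identity gate: the ungated phase-one behaviour, kept for A/B comparisons."""
    return cloud
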