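"""Exception hierarchy.

Every failure mode that callers are expected to handle has its own class so
the CLI can map them to distinct exit codes.
"""


class LapregError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(LapregError):
    """Non-finite coordinates or an otherwise unusable geometric input."""


class InvalidPoseError(LapregError):
    """A supplied rotation/translation does not describe a rigid transform."""


class BehindCameraError(LapregError):
    """Attempted to project a point with non-positive camera-frame depth."""


class DegenerateGeometryError(LapregError):
    """Triangulation rays (near-)parallel; no well-conditioned intersection."""


class EmptyReconstructionError(LapregError):
    """Every stereo correspondence failed to triangulate."""


class GenerationError(LapregError):
    """Synthetic-scene parameters produce invalid (self-intersecting) geometry."""


class EmptyObservationError(LapregError):
    """No surface is visible from the requested viewpoint."""


class DegenerateFitError(LapregError):
    """Point sets too small or rank-deficient for a rigid least-squares fit."""


class NoCorrespondenceError(LapregError):
    """No source/model point pair survives the correspondence distance gate."""


class RegistrationFailureError(LapregError):
    """ICP did not converge, or converged above the failure RMS threshold.

    Mirrors the intraoperative error message contract: the partial result is
    attached so callers can inspect the residual and the iteration history.
    """

    def __init__(self, message, result=None):
        super().__init__(message)
        self.result = result


class EmptyInputError(LapregError):
    """An operation requiring at least one element received none."""


class InsufficientDataError(LapregError):
    """Too few observations for the requested statistic."""


class UnsupportedSampleSizeError(LapregError):
    """Sample size outside the supported range of an approximation."""


class SchemaError(LapregError):
    """A table or config violates its documented schema."""


class FormatError(LapregError):
    """A file could not be parsed; carries line context where available."""

    def __init__(self, message, path=None, line=None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line
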