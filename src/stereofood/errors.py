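"""Exception hierarchy for the stereo food-volume pipeline.

Every stage failure is a distinct, named error so the pipeline driver can
fail fast with an actionable message naming the stage that gave up.
"""


class StereoFoodError(Exception):
    """Base class for all package errors."""


class InputError(StereoFoodError):
    """Unreadable, missing or undecodable input (image, calibration, CSV)."""


class ParameterError(StereoFoodError, ValueError):
    """A tunable was given an out-of-contract value."""


class UsageError(StereoFoodError):
    """API called out of order (e.g. applying a metric scale twice)."""


class DegeneracyError(StereoFoodError):
    """Too few or degenerately configured points for an estimation step."""


class EstimationFailureError(StereoFoodError):
    """A robust estimator could not find any acceptable model."""


class RelevanceGateError(StereoFoodError):
    """The image pair produced fewer matches than the relevance gate requires."""


class CardNotFoundError(StereoFoodError):
    """The reference card could not be detected in an image."""


class RectificationError(StereoFoodError):
    """Stereo rectification failed (numerically degenerate baseline)."""


class AmbiguousPoseError(StereoFoodError):
    """Cheirality could not disambiguate the relative pose."""


class EmptyFoodError(StereoFoodError):
    """No reconstructed points above the table plane; reconstruction failed."""


class DegenerateGeometryError(StereoFoodError):
    """Coplanar/collinear point set where a full-dimensional one is required."""


class SceneGenerationError(StereoFoodError):
    """A synthetic scene could not be rendered under the given spec."""
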