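"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: :class:`InvalidInputError` and
:class:`InvalidConfigurationError` exit with code 2, :class:`NoViableModelError`
(and an uncaught :class:`NoFeaturesSurviveError`) with code 3.
"""

from __future__ import annotations


class DcforestError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(DcforestError, ValueError):
    """Raised when user-supplied data violates a precondition."""


class InvalidConfigurationError(DcforestError, ValueError):
    """Raised when an experiment configuration is unusable (e.g. a
    covariance matrix that is not positive definite)."""


class NoFeaturesSurviveError(DcforestError, RuntimeError):
    """Raised when a screening threshold eliminates every feature, so no
    forest can be grown.

    Attributes
    ----------
    threshold : float
        The threshold that emptied the selection.
    max_score : float
        The largest dependence score observed in the profile.
    """

    def __init__(self, threshold: float, max_score: float):
        self.threshold = float(threshold)
        self.max_score = float(max_score)
        super().__init__(
            f"no features survive threshold {threshold:g}: "
            f"maximum observed score is {max_score:.6g}"
        )


class NoViableModelError(DcforestError, RuntimeError):
    """Raised when every threshold of a sweep produced an empty selection,
    so there is no model to pick a best threshold from."""
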