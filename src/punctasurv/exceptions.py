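"""Exception types shared across the pipeline."""


class PunctasurvError(Exception):
    """Base class for package-specific errors."""


class UndefinedCVError(PunctasurvError, ValueError):
    """Raised when a coefficient of variation cannot be computed.

    Signals an ROI that is unusable for aggregate classification (fewer than
    two pixels, or non-positive mean after background subtraction).
    """


class NoUsableROIError(PunctasurvError, ValueError):
    """Raised when a neuron has no live ROI with a defined CV."""


class ConvergenceError(PunctasurvError, RuntimeError):
    """Raised when Newton-Raphson fails to converge.

    Typically caused by a monotone partial likelihood: a covariate that
    perfectly separates events from non-events drives a coefficient to
    infinity.
    """


class UndefinedCoefficientError(PunctasurvError, ValueError):
    """Raised when a colocalization coefficient has a zero denominator or a
    constant channel."""
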