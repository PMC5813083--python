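"""Exception hierarchy.

``ValidationError`` covers malformed inputs (CLI exit code 2);
``NumericalDegeneracyError`` and its subclasses cover well-formed inputs
on which the computation is mathematically degenerate (CLI exit code 3).
"""


class ValidationError(ValueError):
    """Input violates a documented precondition or invariant."""


class SchemaError(ValidationError):
    """A serialized container is missing a required dataset or attribute."""


class NumericalDegeneracyError(RuntimeError):
    """The computation is degenerate for this (otherwise valid) input."""


class SingularFitError(NumericalDegeneracyError):
    """Rank-deficient autoregressive design matrix.

    Carries the (roi, lag) block whose regressor column is implicated.
    """

    def __init__(self, message: str, roi: str | None = None, lag: int | None = None):
        super().__init__(message)
        self.roi = roi
        self.lag = lag


class DegenerateModelError(NumericalDegeneracyError):
    """Model parameters make the requested statistic undefined (e.g. zero noise variance)."""


class UnstableModelError(NumericalDegeneracyError):
    """A generative model request whose companion spectral radius is >= 1."""

    def __init__(self, message: str, spectral_radius: float | None = None):
        super().__init__(message)
        self.spectral_radius = spectral_radius
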