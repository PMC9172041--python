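"""Exception hierarchy shared across the package."""


class SingleHitError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SingleHitError, ValueError):
    """A parameter violates its documented precondition."""


class ConfigurationError(SingleHitError, ValueError):
    """A configuration object is internally inconsistent."""


class FormatError(SingleHitError, IOError):
    """An on-disk container is missing required datasets or attributes."""


class BoundsError(SingleHitError, IndexError):
    """An index, crop window or schedule position lies outside its valid range."""


class DataError(SingleHitError, ValueError):
    """Input data cannot support the requested operation (e.g. empty class)."""


class TrainingError(SingleHitError, RuntimeError):
    """Optimization failed (non-finite loss); carries the iteration index."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


class ContrastUndefinedError(SingleHitError, ValueError):
    """Too few PSD extrema to evaluate the fringe-contrast metric."""

    def __init__(self, message: str, n_pairs_found: int = 0):
        super().__init__(message)
        self.n_pairs_found = n_pairs_found


class SizeUndeterminedError(SingleHitError, ValueError):
    """No usable fringes / fit for particle-size estimation on a pattern."""
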