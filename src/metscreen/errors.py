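"""Exception types shared across the package."""


class MetscreenError(Exception):
    """Base class for all package errors."""


class ValidationError(MetscreenError, ValueError):
    """An input or configuration value violates a documented contract."""


class InsufficientDataError(MetscreenError, ValueError):
    """Too few observations for the requested fit (e.g. n < K, <2 timepoints)."""


class DegenerateDataError(MetscreenError, ValueError):
    """Data admit no meaningful fit (e.g. all values identical with K > 1)."""


class ModelError(MetscreenError, RuntimeError):
    """A model could not be estimated (singular design, failed optimisation)."""
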