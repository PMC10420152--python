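"""Exception types shared across the package."""


class AlbindError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AlbindError, ValueError):
    """A delimited-text spectrum/titration file is malformed.

    The message names the offending row or column where possible.
    """


class DomainError(AlbindError, ValueError):
    """An argument lies outside the physically meaningful domain."""


class InsufficientDataError(AlbindError, ValueError):
    """Too few usable points to perform the requested fit."""


class FitError(AlbindError, RuntimeError):
    """A nonlinear fit failed to converge; carries the last residual norm."""

    def __init__(self, message: str, residual_norm: float | None = None):
        super().__init__(message)
        self.residual_norm = residual_norm
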