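"""Exception hierarchy shared by all analysis stages."""


class FolatekinError(Exception):
    """Base class for all package errors."""


class ParameterDomainError(FolatekinError, ValueError):
    """A model parameter violates its domain (e.g. non-positive constant)."""


class InputError(FolatekinError, ValueError):
    """A user-supplied input (table, config, argument) is invalid."""


class FitError(FolatekinError, RuntimeError):
    """A regression could not be performed (too few points, degenerate data)."""


class SolverError(FolatekinError, RuntimeError):
    """A numerical solver failed to converge; carries a residual report."""

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals
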