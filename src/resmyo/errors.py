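"""Exception hierarchy shared across the package."""


class ResmyoError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(ResmyoError, ValueError):
    """A tensor, profile, or geometry argument violates a precondition."""


class ConfigurationError(ResmyoError, ValueError):
    """A configuration value, model name, or parameter file is inadmissible."""


class SolverError(ResmyoError, RuntimeError):
    """A root solve or boundary-value solve failed to produce a solution."""


class ConvergenceError(SolverError):
    """An iterative scheme exceeded its budget or diverged.

    Carries the iteration history so callers can inspect the failure.
    """

    def __init__(self, message: str, history=None):
        super().__init__(message)
        self.history = history
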