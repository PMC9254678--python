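"""Exception hierarchy shared across the package."""


class FishAMRError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(FishAMRError, ValueError):
    """A configuration object violates its invariants."""


class InputError(FishAMRError, ValueError):
    """An input record or table violates a contract of the operation."""


class ConvergenceError(FishAMRError, RuntimeError):
    """An MCMC fit failed its convergence diagnostics.

    The partially diagnosed fit is attached as ``.fit`` so the draws can
    still be inspected.
    """

    def __init__(self, message, fit=None):
        super().__init__(message)
        self.fit = fit
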