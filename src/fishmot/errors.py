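"""Exception types shared across the package."""


class FishmotError(Exception):
    """Base class for package errors."""


class InvalidInputError(FishmotError, ValueError):
    """Input violates a documented precondition."""


class DegenerateSampleError(FishmotError, ValueError):
    """Sample has no usable variation (e.g. all values equal)."""


class InsufficientDataError(FishmotError, ValueError):
    """Not enough observations of the required kind."""


class PackingError(FishmotError, ValueError):
    """Objects cannot be placed without overlap at the requested density."""


class DegenerateDesignError(FishmotError, ValueError):
    """Regression design is rank-deficient (e.g. constant predictor)."""


class ConvergenceError(FishmotError, RuntimeError):
    """MCMC diagnostics indicate non-convergence."""
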