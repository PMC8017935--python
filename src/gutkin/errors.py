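"""Exception and warning types shared across the package."""


class GutkinError(Exception):
    """Base class for all package errors."""


class ParameterError(GutkinError, ValueError):
    """A simulation or model parameter is outside its valid domain."""


class DataError(GutkinError, ValueError):
    """An input table or panel violates the schema or its invariants."""


class UndefinedRelatednessError(DataError):
    """Relatedness is undefined because the pooled population is monomorphic
    (across-host similarity equal to one)."""


class SimulationError(GutkinError, RuntimeError):
    """A generative model could not produce a valid draw (e.g. a degenerate
    phylogenetic covariance)."""


class ConfigurationError(GutkinError, ValueError):
    """A pipeline or synthesis step is missing a required component."""


class DiagnosticError(GutkinError, ValueError):
    """A convergence diagnostic was requested on inadequate input."""


class NumericalError(GutkinError, ArithmeticError):
    """A linear-algebra step failed (singular or ill-conditioned matrix)."""


class ConvergenceWarning(UserWarning):
    """An MCMC chain failed a convergence check (e.g. PSRF > 1.1)."""


class CollinearityWarning(UserWarning):
    """A fixed-effect design matrix is rank deficient; the affected
    coefficients are not identified by the data."""
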