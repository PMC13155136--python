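"""Exception hierarchy for limiting dilution assay analysis.

Every error raised by the package derives from :class:`LDAError`, so callers
(and the command-line layer, which maps each class to a distinct exit code)
can catch domain failures without masking programming errors.
"""


class LDAError(Exception):
    """Base class for all domain errors."""


class InputError(LDAError, ValueError):
    """Malformed user input (bad file, bad argument value)."""


class SchemaError(InputError):
    """A required column could not be resolved in an input table."""


class ValidationError(InputError):
    """A row or observation violates the data-type invariants."""


class PoolingError(InputError):
    """Replicates cannot be pooled because their dilution series differ."""


class EstimationRefusedError(LDAError):
    """Estimation is declined on principle.

    The generalized model cannot report a clonogenic activity when not a
    single well exhibits clonogenic growth for a condition: the intercept is
    then unbounded below and any number would be arbitrary.
    """


class ConvergenceWarning(UserWarning):
    """The optimizer stopped without meeting the convergence tolerance."""


class UnboundedIntervalWarning(UserWarning):
    """A confidence bound could not be located and is reported unbounded."""
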