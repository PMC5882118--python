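"""Exception hierarchy shared across the package."""


class SgusError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SgusError, ValueError):
    """A configuration or function parameter is out of its valid range."""


class DataError(SgusError, ValueError):
    """Input data violate a precondition (missing gland, unknown item, ...)."""


class CohortValidationError(DataError):
    """A cohort file failed validation.

    Attributes
    ----------
    errors : list of (line, column, message)
        One entry per offending cell, with 1-based file line numbers.
    """

    def __init__(self, errors):
        self.errors = list(errors)
        lines = "; ".join(
            f"line {ln}, column {col}: {msg}" for ln, col, msg in self.errors[:20]
        )
        more = "" if len(self.errors) <= 20 else f" (+{len(self.errors) - 20} more)"
        super().__init__(f"cohort validation failed: {lines}{more}")
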