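"""Exception hierarchy shared across the package."""


class RCTimeError(Exception):
    """Base class for all package errors."""


class DomainError(RCTimeError, ValueError):
    """An input is outside the physical/mathematical domain of an operation."""


class CompletenessError(RCTimeError, ValueError):
    """A required measurement is missing."""


class ContractError(RCTimeError, ValueError):
    """Two objects passed together violate a caller contract (e.g. non-nested fits)."""


class ConvergenceError(RCTimeError, RuntimeError):
    """An iterative fit failed to converge within its iteration budget."""

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


class InfeasibleDesignError(RCTimeError, ValueError):
    """A study design cannot achieve the requested property (e.g. zero effect size)."""


class SchemaError(RCTimeError, ValueError):
    """A data file does not conform to the expected column schema."""


class SpecInfeasibleError(RCTimeError, ValueError):
    """A synthetic-cohort spec rejects essentially every draw."""
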