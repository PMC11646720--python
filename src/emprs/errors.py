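"""Exception hierarchy for the pipeline."""


class EmprsError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(EmprsError, ValueError):
    """A configuration value violates its documented constraints."""


class InvalidInputError(EmprsError, ValueError):
    """An input value (counts, summaries, matrices) is malformed."""


class EmptyInputError(EmprsError, ValueError):
    """An operation received an empty matrix or vector it cannot act on."""


class DegenerateTableError(EmprsError, ValueError):
    """A contingency table has a zero margin or an all-zero line."""


class CalibrationError(EmprsError, RuntimeError):
    """The liability-to-age calibration could not reach the target prevalence.

    Carries a ``diagnostics`` dict with the achieved prevalence, the target
    and the tolerance that was violated.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ResourceLimitError(EmprsError, RuntimeError):
    """An exact computation would exceed its enumeration guard limit."""


class UndefinedStatisticError(EmprsError, ValueError):
    """The requested statistic is undefined for this input (e.g. single-class AUC)."""
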