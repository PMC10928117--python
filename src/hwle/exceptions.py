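"""Exception types shared across the package."""


class HWLEError(Exception):
    """Base class for package errors."""


class ValidationError(HWLEError):
    """Panel data failed validation (bad state codes, ages, duplicates, empty cohort)."""


class MissingDataError(HWLEError):
    """A computation needs complete data but found missing cells.

    Raised by the likelihood machinery when a model covariate or state is
    missing at an interview; callers should either impute (``hwle.impute``)
    or request complete-case handling explicitly.
    """


class ConvergenceError(HWLEError):
    """All model fits failed to converge where at least one was required."""
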