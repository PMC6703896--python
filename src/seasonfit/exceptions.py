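"""Exception hierarchy for seasonfit.

All data/contract violations derive from :class:`SeasonfitError` so callers
can catch the package's own failures separately from programming errors.
Most also derive from :class:`ValueError` to behave naturally in generic code.
"""


class SeasonfitError(Exception):
    """Base class for all seasonfit errors."""


class MissingMonthError(SeasonfitError, ValueError):
    """A calendar month inside the requested range has no count row.

    The AR(1) error recursion is undefined across gaps, so missing months
    are a hard error; there is no imputation mode.
    """


class DuplicateMonthError(SeasonfitError, ValueError):
    """More than one count row for the same (year, month, sex, age group)."""


class SingularDesignError(SeasonfitError, ValueError):
    """The (transformed) regression design is rank-deficient.

    Raised instead of silently regularising, e.g. for a constant series.
    """


class RhoSamplingError(SeasonfitError, RuntimeError):
    """Rejection sampling of the AR coefficient exhausted its attempt cap
    without landing in the stationarity region."""


class UndefinedPeakError(SeasonfitError, ValueError):
    """Peak month requested for a zero seasonal vector (no phase exists)."""
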