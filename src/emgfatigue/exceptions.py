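"""Exception hierarchy for the emgfatigue package.

All package errors derive from :class:`EMGFatigueError` so callers can
catch everything in one clause; subclasses distinguish input-format
problems from analysis preconditions and statistical-design defects.
"""


class EMGFatigueError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(EMGFatigueError):
    """A delimited file or header does not follow the expected layout."""


class SamplingError(EMGFatigueError):
    """The time column implies a non-uniform or inconsistent sampling rate."""


class ValidationError(EMGFatigueError):
    """A domain object violates one of its invariants."""


class ParameterError(EMGFatigueError):
    """A configuration parameter is outside its valid range."""


class AnalysisError(EMGFatigueError):
    """An analysis precondition is not met (e.g. too little data)."""


class MedianFrequencyError(AnalysisError):
    """The median frequency is undefined (zero in-band power)."""


class FitError(AnalysisError):
    """Too few usable points for a regression fit."""


class NormalizationError(AnalysisError):
    """A normalization denominator (e.g. the IMF) is non-positive."""


class DesignError(EMGFatigueError):
    """A statistical design requirement is violated (cells, balance, days)."""


class MethodError(DesignError):
    """The requested estimator cannot be applied to this design."""
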