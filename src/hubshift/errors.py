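"""Exception hierarchy for the hubshift pipeline.

Every stage raises a subclass of :class:`HubshiftError` so drivers can abort
with a stage-named message rather than a bare ``ValueError``.
"""


class HubshiftError(Exception):
    """Base class for all pipeline errors."""


class FormatError(HubshiftError):
    """A file does not follow the documented tabular dialect."""


class ValidationError(HubshiftError):
    """A loaded object violates a structural invariant (e.g. duplicate ids)."""


class ShapeError(HubshiftError):
    """Array dimensions disagree between objects that must align."""


class DataError(HubshiftError):
    """Non-finite or otherwise unusable values in an input."""


class CoverageError(HubshiftError):
    """A label image does not cover every atlas node."""


class ParameterError(HubshiftError):
    """A filter or analysis parameter is outside its valid range."""


class DegenerateSeriesError(HubshiftError):
    """A region time series has zero variance; correlation is undefined."""


class InsufficientDataError(HubshiftError):
    """Too few subjects or timepoints for the requested statistic."""


class ScenarioError(HubshiftError):
    """A synthetic scenario is internally inconsistent or infeasible."""


class ConfigError(HubshiftError):
    """A pipeline configuration file is missing or malformed."""
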