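"""Exception hierarchy for the orgnet pipeline.

Every stage raises a subclass of :class:`OrgnetError`, so callers (and the
CLI) can distinguish bad input data from bad configuration without matching
on message text.
"""


class OrgnetError(Exception):
    """Base class for all orgnet errors."""


class ConfigurationError(OrgnetError):
    """A configuration value is invalid (probability out of range, empty sector set, ...)."""


class DataError(OrgnetError):
    """Input data are inconsistent with the roster or with themselves."""


class ValidationError(DataError):
    """A structural validation failed (non-binary matrix, unknown layer, self-tie, ...)."""


class UndefinedMetricError(OrgnetError):
    """A metric is requested for a network too small for it to be defined."""
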