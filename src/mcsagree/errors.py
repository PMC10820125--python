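"""Exception hierarchy for mcsagree."""


class MCSError(Exception):
    """Base class for all mcsagree errors."""


class SchemaError(MCSError):
    """A required column is missing or the column mapping is unusable."""


class ParseError(MCSError):
    """A value cell could not be parsed as a number."""


class DesignError(MCSError):
    """The study design is invalid (too few subjects/methods, broken linkage)."""


class LinkageError(MCSError):
    """An operation requiring linked data was called on unlinked data."""


class InsufficientDataError(MCSError):
    """Not enough matched pairs/replicates for the requested statistic."""


class NumericalDomainError(MCSError):
    """A parameter point produced a non-finite or non-PD covariance."""


class DegenerateDataError(MCSError):
    """Data carry no variation; variance components are unidentifiable."""


class ConvergenceError(MCSError):
    """The optimizer failed to converge and no fallback applied."""


class ConfigError(MCSError):
    """Invalid simulation or pipeline configuration."""
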