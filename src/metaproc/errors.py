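"""Exception hierarchy for the processing pipeline.

Every stage raises a subclass of :class:`MetaprocError` so callers (and the
pipeline runner) can distinguish user-facing problems from genuine bugs.
"""


class MetaprocError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(MetaprocError):
    """A tabular input file does not have the expected layout or columns."""


class ValidationError(MetaprocError):
    """Input data violates an invariant (duplicate ids, negative intensity...)."""


class ConfigurationError(MetaprocError):
    """A stage was asked to run with an unusable configuration
    (e.g. QC-based filtering on a run with no QC samples)."""


class ParameterError(MetaprocError):
    """A parameter value is out of range or inconsistent."""


class ComputationError(MetaprocError):
    """A well-configured stage hit degenerate data it cannot process
    (e.g. a sample with no usable quotients during PQN)."""


class FormulaError(MetaprocError):
    """An elemental formula could not be parsed."""
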