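"""Exception hierarchy for cochnet.

Every user-facing failure derives from :class:`CochnetError` so callers can
catch one type at the pipeline boundary.
"""


class CochnetError(Exception):
    """Base class for all cochnet errors."""


class ConfigError(CochnetError):
    """A configuration value is out of range or inconsistent."""


class DesignError(CochnetError):
    """The sample design is invalid (e.g. fewer than 2 replicates in a group)."""


class ScaleError(CochnetError):
    """An operation was applied to an expression matrix on the wrong scale."""


class AlignmentError(CochnetError):
    """Expression columns and sample metadata do not match."""


class ValidationError(CochnetError):
    """Input data violates a structural invariant (duplicates, negatives...)."""


class BundleError(CochnetError):
    """A bundle directory is missing a component or cannot be written."""


class ParseError(CochnetError):
    """A text input (GMT, edge list) is malformed."""


class StageError(CochnetError):
    """A pipeline stage is missing an upstream artifact."""
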