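"""Typed exceptions raised across the pipeline.

Every reader and operation either returns a valid object or raises one of
these; nothing is silently coerced.
"""


class FfeprofError(Exception):
    """Base class for all package errors."""


class SchemaError(FfeprofError):
    """A table is missing required columns or has malformed values."""


class IntegrityError(FfeprofError):
    """A table parses but violates a content invariant (duplicates,
    negative intensities, out-of-vocabulary labels, ...)."""


class ConfigError(FfeprofError):
    """An invalid simulation or run configuration."""


class UsageError(FfeprofError):
    """An operation was applied to data at the wrong processing level."""


class EmptyWindowError(FfeprofError):
    """No sample has positive OD280; an analysis window cannot be chosen."""
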