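"""Exception hierarchy shared across the package.

All package-specific failures derive from :class:`FtdaError` so callers can
catch one base class; subclasses additionally derive from the closest builtin
(``ValueError``, ``KeyError``, ``IOError``) so idiomatic ``except`` clauses
keep working.
"""


class FtdaError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(FtdaError, ValueError):
    """An in-memory object violates one of its invariants."""


class CorpusAlignmentError(ValidationError):
    """Row counts of corpus components disagree."""


class ContainerError(FtdaError, IOError):
    """An on-disk container is missing a component or is corrupt."""


class IncompatibleArtifactError(ContainerError):
    """A stored artifact has an unsupported format or schema version."""


class ConfigurationError(FtdaError, ValueError):
    """A pipeline or task configuration is incomplete or inconsistent."""


class TruncationError(FtdaError, ValueError):
    """A text exceeds the configured maximum token length.

    Raised explicitly instead of silently truncating, so that reconstruction
    targets are never corrupted without the caller noticing.
    """


class PipelineError(FtdaError, RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


class DegenerateDataError(FtdaError, ValueError):
    """The data cannot support the requested operation (e.g. all rows equal)."""
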