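"""Exception hierarchy.

Validation failures (bad configs, schema violations) raise
:class:`ValidationError`; pipeline-stage failures that exclude a record
(too short, contains missing samples) raise the dedicated subclasses so the
driver can log and skip the case rather than abort.
"""


class CowaveError(Exception):
    """Base class for all package errors."""


class ValidationError(CowaveError, ValueError):
    """A config field, schema, or precondition is invalid."""


class RecordTooShortError(CowaveError):
    """Record shorter than the requested analysis window; case is excluded."""


class MissingValuesError(CowaveError):
    """Record or window contains undefined (NaN) samples; case is excluded."""


class ConstantInputError(CowaveError):
    """A statistic is undefined because an input sequence is constant."""


class TrainingDivergedError(CowaveError):
    """Training produced a non-finite loss."""
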