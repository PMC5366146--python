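"""Exception hierarchy.

Every error raised by the package derives from :class:`CofunmirError` so
callers can catch the whole family with one clause.
"""


class CofunmirError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CofunmirError):
    """An input object violates a precondition (empty, wrong shape, ...)."""


class UnknownIdError(CofunmirError, KeyError):
    """An entity id could not be resolved (ontology term, similarity index...)."""


class MissingAnnotationError(CofunmirError):
    """An entity has no (or an empty) gene-set annotation."""


class AlignmentError(CofunmirError):
    """Two matrices that must share an id index do not."""


class InvalidWeightsError(CofunmirError):
    """Nucleotide weight table is incomplete or non-positive."""


class DegenerateWeightsError(CofunmirError):
    """All nucleotide weights equal: zero variance, normalization undefined."""


class SequenceError(CofunmirError):
    """A sequence is too short or contains characters outside A/C/G/U/T."""


class ConfigError(CofunmirError):
    """An unknown mode/option value."""


class ParseError(CofunmirError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class DegenerateTrainingError(CofunmirError):
    """Training set contains a single class."""


class SamplingError(CofunmirError):
    """A sampling request cannot be satisfied (pool too small, ...)."""


class InvalidPairError(CofunmirError):
    """A miRNA pair is invalid (self-pair)."""


class SpecError(CofunmirError):
    """A synthetic fixture specification is infeasible."""
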