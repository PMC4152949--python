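"""Exception hierarchy for dhspred.

Every error raised on purpose by the package derives from :class:`DhspredError`
so callers (and the CLI) can distinguish expected failure modes from bugs.
"""


class DhspredError(Exception):
    """Base class for all dhspred errors."""


class FastaParseError(DhspredError):
    """Malformed FASTA input (bad header, empty record, ...)."""


class SequenceValidationError(DhspredError):
    """A residue outside the accepted alphabet, or a sequence too short."""


class DatasetError(DhspredError):
    """Inconsistent labeled dataset (label mismatch, duplicate ids, ...)."""


class DegeneratePropertyError(DhspredError):
    """A structural property with zero variance across the 16 dinucleotides."""


class SequenceTooShortError(SequenceValidationError):
    """Sequence length insufficient for the requested correlation tier count."""


class EncodingError(DhspredError):
    """Aggregate failure while encoding a dataset; carries offending ids."""

    def __init__(self, message: str, failed_ids=()):
        super().__init__(message)
        self.failed_ids = tuple(failed_ids)


class TrainingError(DhspredError):
    """SVM training impossible (single-class input, bad parameters, ...)."""


class DimensionMismatchError(DhspredError):
    """Feature matrix width does not match the trained model."""


class EvaluationError(DhspredError):
    """Invalid evaluation protocol configuration (fold count, empty counts)."""


class ModelIOError(DhspredError):
    """Model archive unreadable, or property-table checksum mismatch."""
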