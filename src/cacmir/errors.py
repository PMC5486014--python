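"""Exception hierarchy shared across the pipeline stages."""


class CacmirError(Exception):
    """Base class for all package errors."""


class ParameterError(CacmirError, ValueError):
    """A function argument violates its documented constraints."""


class SequenceError(CacmirError, ValueError):
    """A sequence contains characters outside the {A,C,G,T,U,N} alphabet."""


class FastaFormatError(CacmirError, ValueError):
    """A FASTA file is structurally malformed (reports the offending line)."""


class FastaRecordError(CacmirError, ValueError):
    """A FASTA record is invalid (e.g. empty sequence body)."""


class FixtureError(CacmirError, RuntimeError):
    """A packaged fixture table does not match its manifest."""


class AlignmentError(CacmirError, ValueError):
    """miRNA/site lengths disagree in a positional alignment."""


class NamingError(CacmirError, ValueError):
    """A miRNA name does not follow the species-prefix naming pattern."""


class NumericalError(CacmirError, RuntimeError):
    """An iterative numerical routine failed to converge."""
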