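"""Exceptions raised by the pipeline."""


class XbpTargetsError(Exception):
    """Base class for all package errors."""


class MalformedIntervalError(XbpTargetsError):
    """An interval violates 0 <= start < end or has an empty chromosome name."""


class InvalidSequenceError(XbpTargetsError):
    """A nucleotide sequence contains characters outside {A, C, G, T, N}."""


class InvalidMotifError(XbpTargetsError):
    """A motif pattern contains a character that is not an IUPAC code."""


class MissingReferenceError(XbpTargetsError):
    """A qPCR reference gene is absent from a condition."""


class UndefinedCorrelationError(XbpTargetsError):
    """Pearson correlation requested on a zero-variance vector."""


class InfeasiblePackingError(XbpTargetsError):
    """The simulator cannot place the requested motif instances in a region."""
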