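"""Exception hierarchy for catseq."""


class CatSeqError(Exception):
    """Base class for all catseq errors."""


class SequenceAlphabetError(CatSeqError, ValueError):
    """A sequence contains a character outside the DNA alphabet {A, C, G, T}."""


class FastaFormatError(CatSeqError, ValueError):
    """A FASTA file is malformed (bad header, empty/duplicate record, bad base)."""


class ProfileComputationError(CatSeqError, ArithmeticError):
    """Profile arithmetic failed; carries the accumulator state for diagnosis."""

    def __init__(self, message: str, accumulators=None):
        super().__init__(message)
        self.accumulators = accumulators


class ProvenanceMismatchError(CatSeqError, ValueError):
    """Two profiles were built under different scoring/benchmark conventions
    and therefore must not be compared."""


class SchemaError(CatSeqError, ValueError):
    """A profile sidecar file has an unknown schema version or bad structure."""
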