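"""Exception hierarchy for input validation and domain errors."""


class TrioPriorError(Exception):
    """Base class for all package errors."""


class InputFormatError(TrioPriorError):
    """A standard-format input file violates its dialect or an invariant."""


class MissingSampleError(InputFormatError):
    """A pedigree sample is absent from the VCF header."""


class PedigreeError(InputFormatError):
    """Pedigree structure is invalid or unusable for the requested filter."""


class NonCodingPositionError(TrioPriorError):
    """A genomic position falls outside the coding sequence of a transcript."""


class ReferenceMismatchError(TrioPriorError):
    """The stated reference base disagrees with the transcript coding sequence."""

    def __init__(self, expected: str, observed: str, c_pos: int):
        self.expected = expected
        self.observed = observed
        self.c_pos = c_pos
        super().__init__(
            f"reference mismatch at c.{c_pos}: transcript has {expected!r}, "
            f"variant claims {observed!r}"
        )


class HgvsParseError(TrioPriorError):
    """An HGVS c. substitution string could not be parsed."""


class NoScoresError(TrioPriorError):
    """Predictor-score classification was requested with no scores present."""
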