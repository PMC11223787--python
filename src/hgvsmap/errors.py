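"""Typed errors shared across the toolbox.

Every error that a caller may want to turn into a machine-readable
response carries a short ``kind`` string; the service layer maps any
:class:`HgvsmapError` to a 400 envelope with that kind.
"""

from __future__ import annotations


class HgvsmapError(Exception):
    """Base class for all toolbox errors."""

    kind: str = "error"

    def __init__(self, message: str):
        super().__init__(message)
        self.message = message


class FileLoadError(HgvsmapError):
    """A snapshot file could not be parsed (bad format, duplicate record...)."""

    kind = "load-error"


class AlphabetError(HgvsmapError):
    """A sequence contains a character outside its declared alphabet."""

    kind = "alphabet-error"


class ValidationError(HgvsmapError):
    """A data model invariant is violated (exon overlap, CDS length...)."""

    kind = "validation-error"


class CoordinateError(HgvsmapError):
    """A position falls outside the addressable range."""

    kind = "coordinate-error"


class UnknownChromosomeError(HgvsmapError):
    kind = "unknown-chromosome"


class UnknownGeneError(HgvsmapError):
    kind = "unknown-gene"


class AmbiguousReferenceError(HgvsmapError):
    """An operation needs a concrete base but the reference holds an N."""

    kind = "ambiguous-reference"


class TranslationError(HgvsmapError):
    """The coding sequence cannot be translated (internal stop, no stop...)."""

    kind = "translation-error"


class HgvsSyntaxError(HgvsmapError):
    """Variant text does not match the supported grammar.

    ``offset`` is the 0-based character position where parsing failed.
    """

    kind = "hgvs-syntax-error"

    def __init__(self, message: str, offset: int = 0):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


class UnknownAminoAcidError(HgvsmapError):
    kind = "unknown-amino-acid"


class ReferenceMismatchError(HgvsmapError):
    """A supplied ref allele or amino acid disagrees with the loaded
    reference — the signature of stale or mismatched annotation."""

    kind = "reference-mismatch"

    def __init__(self, message: str, expected: str = "", observed: str = ""):
        super().__init__(message)
        self.expected = expected
        self.observed = observed


class IntronicPositionError(HgvsmapError):
    kind = "intronic-position"


class UtrPositionError(HgvsmapError):
    kind = "utr-position"


class SynonymousRequestError(HgvsmapError):
    """Reverse translation was asked for the amino acid the reference
    codon already encodes; the zero-change self-candidate is excluded."""

    kind = "synonymous-request"


class FusionError(HgvsmapError):
    kind = "fusion-error"


class ChainParseError(HgvsmapError):
    kind = "chain-parse-error"


class ChainIntegrityError(HgvsmapError):
    kind = "chain-integrity-error"


class GenerationError(HgvsmapError):
    """The fixture generator was given infeasible parameters."""

    kind = "generation-error"
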