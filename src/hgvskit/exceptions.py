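"""Exception hierarchy.

Every error raised by this package derives from :class:`HgvsError` so callers
can catch a single base class.  Syntax problems and genuinely unsupported
nomenclature (uncertain positions, compound alleles, ISCN, ...) are kept
distinct: the former means the string is malformed, the latter means the
string may be legal HGVS that this package deliberately does not model.
"""

from __future__ import annotations


class HgvsError(Exception):
    """Base class for all errors raised by hgvskit."""


class HgvsSyntaxError(HgvsError):
    """The input string does not match the HGVS grammar.

    Carries ``pos``, the 0-based character offset at which parsing failed,
    when known.
    """

    def __init__(self, message: str, pos: int | None = None):
        super().__init__(message)
        self.pos = pos


class UnsupportedVariantError(HgvsError):
    """Legal-but-unsupported nomenclature (uncertain positions, compound
    alleles, mosaic/chimeric variants, translocations, ISCN)."""


class HgvsValidationError(HgvsError):
    """Raised by validators in strict mode when a report is not VALID."""


class ReferenceDisagreementError(HgvsError):
    """The reference allele stated in a variant does not match the sequence."""


class BoundsError(HgvsError):
    """A coordinate lies outside the reference sequence or alignment."""


class DataProviderError(HgvsError):
    """Base class for data-provider failures."""


class SequenceUnavailableError(DataProviderError):
    """No sequence is stored for the requested accession."""


class TranscriptUnavailableError(DataProviderError):
    """No transcript record is stored for the requested accession."""


class FixtureIntegrityError(DataProviderError):
    """A fixture bundle failed its load-time consistency checks."""


class FixtureSpecError(DataProviderError):
    """A synthetic-fixture specification is infeasible."""


class NoCdsError(HgvsError):
    """A CDS-relative (c.) operation was requested on a non-coding transcript."""


class NotOnTranscriptError(HgvsError):
    """A genomic interval does not overlap the transcript's aligned span."""
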