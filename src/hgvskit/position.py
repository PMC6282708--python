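"""Position types for HGVS coordinates.

HGVS positions are 1-based and inclusive and come in several dialects:

* ``g./m.`` — plain positive integers on a genomic sequence;
* ``n.`` — positive integers on a transcript, optionally with an intron
  offset (``n.87+2``);
* ``c.`` — CDS-relative: negative bases are 5' of the translation start
  (``c.-5``), ``*``-anchored bases are 3' of the stop (``c.*3``), and intron
  offsets are allowed (``c.88-1``);
* ``p.`` — amino-acid residue numbers with the residue letter attached.

Internally all arithmetic elsewhere in the package is performed in interbase
(0-based, half-open) coordinates; these classes exist to carry the HGVS
display dialect and to give positions a total ordering so intervals can be
checked for consistency.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .exceptions import HgvsError


class Anchor(enum.Enum):
    """Which CDS landmark a c. base counts from.

    ``CDS_START`` covers both coding positions (base > 0) and 5'-UTR
    positions (base < 0); ``CDS_END`` marks ``*`` (3'-UTR) positions.
    For g./m./n. coordinates the anchor is always ``CDS_START``.
    """

    CDS_START = 0
    CDS_END = 1


@dataclass(frozen=True, order=False)
class BaseOffsetPosition:
    """A 1-based HGVS base position with optional intron offset and anchor.

    ``base`` is never 0: ``c.-1`` directly abuts ``c.1``.  ``offset`` is the
    signed intron offset (0 for exonic or genomic positions).
    """

    base: int
    offset: int = 0
    anchor: Anchor = Anchor.CDS_START

    def __post_init__(self) -> None:
        if self.base == 0:
            raise HgvsError("HGVS base positions are 1-based and never 0")
        if self.anchor is Anchor.CDS_END and self.base < 0:
            raise HgvsError("*-anchored positions are positive")

    @property
    def is_intronic(self) -> bool:
        return self.offset != 0

    @property
    def is_utr(self) -> bool:
        return self.anchor is Anchor.CDS_END or self.base < 0

    def _key(self) -> tuple[int, int, int]:
        # collapse the missing 0 so -1 and 1 are adjacent integers
        linear = self.base if self.base < 0 else self.base - 1
        return (self.anchor.value, linear, self.offset)

    def __lt__(self, other: "BaseOffsetPosition") -> bool:
        self._check(other)
        return self._key() < other._key()

    def __le__(self, other: "BaseOffsetPosition") -> bool:
        self._check(other)
        return self._key() <= other._key()

    def __gt__(self, other: "BaseOffsetPosition") -> bool:
        return not self.__le__(other)

    def __ge__(self, other: "BaseOffsetPosition") -> bool:
        return not self.__lt__(other)

    def _check(self, other: object) -> None:
        if not isinstance(other, BaseOffsetPosition):
            raise HgvsError(
                f"cannot compare {type(self).__name__} with {type(other).__name__}"
            )


def compare_positions(a: BaseOffsetPosition, b: BaseOffsetPosition) -> int:
    """Three-way comparison: -1, 0 or +1.

    Positions compare by (anchor, base, offset); the CDS_START anchor
    precedes CDS_END, so every ``c.*`` position follows every plain CDS
    position.
    """
    if a._key() < b._key():
        return -1
    if a._key() > b._key():
        return 1
    return 0


@dataclass(frozen=True)
class BaseOffsetInterval:
    """Closed HGVS interval; ``start <= end`` under the position ordering."""

    start: BaseOffsetPosition
    end: BaseOffsetPosition = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.end is None:
            object.__setattr__(self, "end", self.start)

    @property
    def is_simple(self) -> bool:
        """True when both ends are exonic, non-UTR positions (plain bases)."""
        return (
            self.start.offset == 0
            and self.end.offset == 0
            and self.start.anchor is Anchor.CDS_START
            and self.end.anchor is Anchor.CDS_START
            and self.start.base > 0
            and self.end.base > 0
        )

    def interbase(self) -> tuple[int, int]:
        """(start, end) in 0-based half-open coordinates; simple intervals only."""
        if not self.is_simple:
            raise HgvsError("interval with offsets/UTR anchors has no plain interbase form")
        return self.start.base - 1, self.end.base

    def span(self) -> int:
        """Number of bases covered, when both ends share anchor and exon context."""
        if self.start.anchor is not self.end.anchor:
            raise HgvsError("span undefined across anchors")
        if self.start.offset == 0 and self.end.offset == 0:
            s, e = self.start.base, self.end.base
            n = e - s + 1
            if s < 0 < e:  # no position 0 in HGVS numbering
                n -= 1
            return n
        if self.start.base == self.end.base:
            return self.end.offset - self.start.offset + 1
        raise HgvsError("span undefined for interval crossing exon boundaries")


def interval_from_interbase(start_i: int, end_i: int) -> BaseOffsetInterval:
    """Build a plain (offset-free) interval from interbase coordinates."""
    return BaseOffsetInterval(
        BaseOffsetPosition(start_i + 1), BaseOffsetPosition(max(end_i, start_i + 1))
    )


@dataclass(frozen=True, order=True)
class AAPosition:
    """A protein residue: 1-letter amino acid + 1-based position."""

    pos: int = field(compare=True)
    aa: str = field(compare=False, default="X")

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise HgvsError("protein positions are 1-based")


@dataclass(frozen=True)
class ProteinInterval:
    start: AAPosition
    end: AAPosition = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.end is None:
            object.__setattr__(self, "end", self.start)
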