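"""The SequenceVariant record: accession + coordinate type + PosEdit.

This is the universal currency passed between parser, validator,
normalizer, and mapper.  Instances are immutable; every manipulation
produces a new variant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .edits import Edit
from .exceptions import HgvsError
from .position import BaseOffsetInterval, ProteinInterval

COORD_TYPES = ("g", "m", "n", "c", "p")

#: accession-prefix compatibility with coordinate types; prefixes not listed
#: are unconstrained (fixture and toy accessions).
AC_PREFIX_TYPES = {
    "NC_": ("g", "m"),
    "NT_": ("g",),
    "NW_": ("g",),
    "NG_": ("g",),
    "NM_": ("c", "n"),
    "NR_": ("n",),
    "NP_": ("p",),
}


@dataclass(frozen=True)
class PosEdit:
    """A position interval plus the edit applied there.

    ``uncertain`` marks predicted consequences (printed in parentheses,
    e.g. ``p.(Gly2Arg)``).
    """

    interval: BaseOffsetInterval | ProteinInterval
    edit: Edit
    uncertain: bool = False


@dataclass(frozen=True)
class SequenceVariant:
    """An HGVS variant: ``<ac>:<type>.<posedit>``."""

    ac: str
    type: str
    posedit: PosEdit

    def __post_init__(self) -> None:
        if not self.ac:
            raise HgvsError("accession must be non-empty")
        if self.type not in COORD_TYPES:
            raise HgvsError(f"unsupported coordinate type {self.type!r}")
        iv = self.posedit.interval
        if self.type == "p":
            if not isinstance(iv, ProteinInterval):
                raise HgvsError("p. variants require protein positions")
        else:
            if not isinstance(iv, BaseOffsetInterval):
                raise HgvsError(f"{self.type}. variants require nucleotide positions")
            if self.type in ("g", "m"):
                if iv.start.offset or iv.end.offset:
                    raise HgvsError("offsets are not allowed on g./m. positions")
                if iv.start.base < 0 or iv.start.is_utr or iv.end.is_utr:
                    raise HgvsError("UTR anchors are not allowed on g./m. positions")
            if self.type == "n" and (iv.start.is_utr or iv.end.is_utr):
                raise HgvsError("UTR anchors are not allowed on n. positions")

    def with_posedit(self, posedit: PosEdit) -> "SequenceVariant":
        return replace(self, posedit=posedit)

    def __str__(self) -> str:
        from .formatter import format_variant  # deferred: formatter imports us

        return format_variant(self)
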