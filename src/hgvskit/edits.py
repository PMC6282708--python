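"""Edit payloads and allele arithmetic.

An :class:`Edit` is a tagged record describing what changes at a position:
substitution, deletion, insertion, deletion-insertion, duplication,
inversion, repeat, conversion, or identity.  ``apply_edit`` plays these
edits onto a concrete sequence and is used throughout the package as the
ground-truth oracle for allele equivalence (normalization and projection
must preserve the edited sequence it produces).
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import BoundsError, HgvsError, ReferenceDisagreementError
from .sequences import reverse_complement

#: edit kinds in HGVS rewrite-priority order (highest first); repeat and
#: conversion sit outside the rewrite rules.
KINDS = ("sub", "del", "inv", "dup", "con", "ins", "delins", "repeat", "identity")


@dataclass(frozen=True)
class Edit:
    """One sequence change.

    ``ref`` may be an explicit sequence (``"T"``), a declared length
    (``174`` for ``del174``), or ``None`` (no reference stated, as in
    ``c.31_35del``); explicit sequence and declared length are mutually
    exclusive by type.  ``alt`` is the inserted/substituted sequence, empty
    or ``None`` where the kind implies it.
    """

    kind: str
    ref: str | int | None = None
    alt: str | None = None
    # repeats: unit sequence and copy count, e.g. CAG[7]
    repeat_unit: str | None = None
    repeat_count: int | None = None
    # conversions: (accession or None, coordinate type or None, interval)
    con_source: tuple | None = None
    # frameshifts (protein only): position of the new stop relative to the
    # first changed residue, None when not applicable, -1 when no stop found
    fs_term: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS and self.kind not in ("ext", "fs", "unknown"):
            raise HgvsError(f"unknown edit kind {self.kind!r}")
        if self.kind == "sub":
            if not (isinstance(self.ref, str) and len(self.ref) == 1
                    and isinstance(self.alt, str) and len(self.alt) == 1):
                raise HgvsError("substitution requires single-base ref and alt")
        if self.kind == "ins" and not self.alt:
            raise HgvsError("insertion requires a non-empty alt")
        if self.kind == "del" and self.alt:
            raise HgvsError("deletion carries no alt")

    @property
    def ref_len(self) -> int | None:
        """Length of the stated reference allele, if any was stated."""
        if isinstance(self.ref, int):
            return self.ref
        if isinstance(self.ref, str):
            return len(self.ref)
        return None


def _check_ref(seq: str, start_i: int, end_i: int, ref: str | int | None) -> None:
    if isinstance(ref, str) and ref and seq[start_i:end_i] != ref:
        raise ReferenceDisagreementError(
            f"stated reference {ref!r} != sequence {seq[start_i:end_i]!r} "
            f"at interbase [{start_i},{end_i})"
        )
    if isinstance(ref, int) and end_i - start_i != ref:
        raise ReferenceDisagreementError(
            f"declared length {ref} != interval span {end_i - start_i}"
        )


def edit_alleles(seq: str, start_i: int, end_i: int, edit: Edit) -> tuple[str, str]:
    """Materialize (ref, alt) allele strings for an edit at interbase
    [start_i, end_i) on ``seq``.  For insertions the interval is the two
    flanking bases and the returned ref is empty.
    """
    if edit.kind == "ins":
        return "", edit.alt or ""
    ref = seq[start_i:end_i]
    _check_ref(seq, start_i, end_i, edit.ref)
    if edit.kind == "sub":
        return ref, edit.alt or ""
    if edit.kind == "del":
        return ref, ""
    if edit.kind == "delins":
        return ref, edit.alt or ""
    if edit.kind == "dup":
        return ref, ref + ref
    if edit.kind == "inv":
        return ref, reverse_complement(ref)
    if edit.kind == "identity":
        return ref, ref
    if edit.kind == "repeat":
        return ref, (edit.repeat_unit or "") * (edit.repeat_count or 0)
    raise HgvsError(f"cannot materialize alleles for edit kind {edit.kind!r}")


def apply_edit(seq: str, interval: tuple[int, int], edit: Edit) -> str:
    """Apply ``edit`` at the 1-based inclusive ``interval`` of ``seq``.

    For insertions the interval names the two flanking bases; the alt is
    spliced between them.  Raises :class:`ReferenceDisagreementError` when an
    explicit ref does not match the sequence and :class:`BoundsError` when
    the interval falls outside ``seq``.
    """
    start, end = interval
    if edit.kind == "ins":
        if end != start + 1:
            raise HgvsError("insertion interval must span two adjacent bases")
        if not (1 <= start <= len(seq)):
            raise BoundsError(f"insertion flanks [{start},{end}] outside 1..{len(seq)}")
        cut = start  # interbase point after `start`
        return seq[:cut] + (edit.alt or "") + seq[cut:]
    if not (1 <= start <= end <= len(seq)):
        raise BoundsError(f"interval [{start},{end}] outside 1..{len(seq)}")
    s_i, e_i = start - 1, end
    ref, alt = edit_alleles(seq, s_i, e_i, edit)
    if edit.kind == "dup":
        return seq[:e_i] + seq[s_i:e_i] + seq[e_i:]
    return seq[:s_i] + alt + seq[e_i:]
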