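"""Two-stage variant validation.

Intrinsic criteria (i1-i5) inspect only the variant record itself; extrinsic
criteria (e1-e3) consult the data provider and therefore run second (they
are the expensive stage and are skipped entirely when intrinsic validation
already found an ERROR).  Every criterion reports one of three levels:

* ``VALID`` — the criterion is satisfied;
* ``ERROR`` — the criterion is violated;
* ``WARNING`` — the criterion cannot be evaluated (classically: an intronic
  position on a transcript with no genomic alignment available, whose
  reference base can be neither confirmed nor refuted).

The default mode records outcomes and never raises; ``strict=True`` raises
:class:`HgvsValidationError` whenever the overall level is not VALID, so
pipelines can treat "plausibly valid" as failure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import mapper as _mapper
from .edits import Edit
from .exceptions import (
    HgvsError,
    HgvsValidationError,
    NotOnTranscriptError,
    TranscriptUnavailableError,
)
from .position import BaseOffsetInterval
from .provider import DataProvider
from .variant import AC_PREFIX_TYPES, SequenceVariant

VALID, WARNING, ERROR = "VALID", "WARNING", "ERROR"
_RANK = {VALID: 0, WARNING: 1, ERROR: 2}


@dataclass
class ValidationReport:
    """Ordered criterion outcomes: (criterion id, level, message)."""

    outcomes: list[tuple[str, str, str]] = field(default_factory=list)

    def add(self, criterion: str, level: str, message: str = "") -> None:
        self.outcomes.append((criterion, level, message))

    @property
    def overall(self) -> str:
        worst = VALID
        for _, level, _ in self.outcomes:
            if _RANK[level] > _RANK[worst]:
                worst = level
        return worst

    def messages(self, level: str | None = None) -> list[str]:
        return [m for _, lvl, m in self.outcomes
                if m and (level is None or lvl == level)]

    def extend(self, other: "ValidationReport") -> None:
        self.outcomes.extend(other.outcomes)

    def to_dict(self) -> dict:
        return {
            "overall": self.overall,
            "outcomes": [
                {"criterion": c, "level": lvl, "message": m}
                for c, lvl, m in self.outcomes
            ],
        }


# --------------------------------------------------------------------------
# intrinsic criteria


def _adjacency(iv: BaseOffsetInterval) -> str:
    """VALID/WARNING/ERROR for 'start and end are adjacent' (insertions)."""
    s, e = iv.start, iv.end
    if s.anchor is not e.anchor:
        # adjacency across the stop codon needs the CDS length
        return WARNING
    if s.offset == 0 and e.offset == 0:
        return VALID if e._key()[1] - s._key()[1] == 1 else ERROR
    if s.base == e.base:
        return VALID if e.offset - s.offset == 1 else ERROR
    if s.offset > 0 and e.offset < 0:
        # both endpoints hang into the same intron interior; the intron
        # length is unknown without alignment data
        return WARNING
    return ERROR


def validate_intrinsic(variant: SequenceVariant) -> ValidationReport:
    """Self-consistency checks requiring no external data."""
    report = ValidationReport()
    pe = variant.posedit
    iv = pe.interval
    edit = pe.edit

    # i1: start <= end
    if variant.type == "p":
        ok = iv.start.pos <= iv.end.pos
    else:
        ok = iv.start <= iv.end
    report.add("i1", VALID if ok else ERROR,
               "" if ok else "interval start follows its end")
    if not ok:
        return report

    # i2: insertion interval spans exactly two adjacent positions
    if edit.kind == "ins":
        if variant.type == "p":
            level = VALID if iv.end.pos - iv.start.pos == 1 else ERROR
        else:
            level = _adjacency(iv)
        report.add("i2", level,
                   "" if level == VALID else
                   "insertion flanks must be adjacent positions")

    # i3: accession prefix compatible with the coordinate type
    for prefix, types in AC_PREFIX_TYPES.items():
        if variant.ac.startswith(prefix):
            if variant.type not in types:
                report.add("i3", ERROR,
                           f"accession prefix {prefix} does not carry "
                           f"{variant.type}. coordinates")
            else:
                report.add("i3", VALID, "")
            break
    else:
        report.add("i3", VALID, "")

    # i4: stated reference length equals the interval span
    if variant.type != "p" and edit.kind in ("del", "dup", "inv", "delins",
                                             "identity", "sub"):
        stated = edit.ref_len
        if stated is not None:
            try:
                span = iv.span()
            except HgvsError:
                report.add("i4", WARNING,
                           "interval span not computable without alignment data")
            else:
                if span != stated:
                    report.add("i4", ERROR,
                               f"interval spans {span} bases but the edit "
                               f"states {stated}")
                else:
                    report.add("i4", VALID, "")

    # i5: edit arity matches its kind
    if variant.type != "p":
        if edit.kind == "sub":
            try:
                span = iv.span()
            except HgvsError:
                span = None
            if span is not None and span != 1:
                report.add("i5", ERROR, "substitution interval must span 1 base")
            else:
                report.add("i5", VALID, "")
        elif edit.kind == "delins" and not edit.alt:
            report.add("i5", ERROR, "deletion-insertion states no inserted bases")
        else:
            report.add("i5", VALID, "")

    return report


# --------------------------------------------------------------------------
# extrinsic criteria


def _stated_ref(edit: Edit) -> str | None:
    return edit.ref if isinstance(edit.ref, str) and edit.ref else None


def validate_extrinsic(variant: SequenceVariant,
                       provider: DataProvider) -> ValidationReport:
    """Checks against provider sequences, exon structures and alignments."""
    report = ValidationReport()
    if variant.type in ("g", "m"):
        _extrinsic_linear(variant, provider, report)
    elif variant.type in ("c", "n"):
        _extrinsic_tx(variant, provider, report)
    else:
        _extrinsic_protein(variant, provider, report)
    return report


def _check_ref_against(report: ValidationReport, stated: str | None,
                       actual: str) -> None:
    if stated is None:
        report.add("e2", VALID, "")
    elif stated != actual:
        report.add("e2", ERROR,
                   f"stated reference {stated!r} disagrees with sequence "
                   f"{actual!r}")
    else:
        report.add("e2", VALID, "")


def _extrinsic_linear(variant: SequenceVariant, provider: DataProvider,
                      report: ValidationReport) -> None:
    iv = variant.posedit.interval
    length = provider.seq_length(variant.ac)
    # an insertion's 3' flank may be the hypothetical base after the sequence
    limit = length + 1 if variant.posedit.edit.kind == "ins" else length
    if not (1 <= iv.start.base and iv.end.base <= limit):
        report.add("e1", ERROR,
                   "the given coordinate is outside the bounds of the "
                   "reference sequence")
        return
    report.add("e1", VALID, "")
    stated = _stated_ref(variant.posedit.edit)
    if stated is not None:
        actual = provider.get_seq(variant.ac, iv.start.base - 1, iv.end.base)
        _check_ref_against(report, stated, actual)
    else:
        report.add("e2", VALID, "")


def _extrinsic_tx(variant: SequenceVariant, provider: DataProvider,
                  report: ValidationReport) -> None:
    iv = variant.posedit.interval
    intronic = bool(iv.start.offset or iv.end.offset)
    provider.seq_length(variant.ac)  # no sequence at all: data error, not a report
    try:
        record = provider.get_transcript(variant.ac)
    except TranscriptUnavailableError:
        record = None

    if variant.type == "c" and record is None:
        report.add("e1", WARNING,
                   "no transcript annotation; CDS coordinates cannot be "
                   "located on the sequence")
        if intronic:
            report.add("e3", WARNING,
                       "intronic sequence cannot be validated or refuted "
                       "without a genomic alignment")
        return

    if variant.type == "c":
        try:
            var_n = _mapper.c_to_n(variant, record)
        except HgvsError as exc:
            report.add("e1", ERROR, f"invalid CDS coordinate: {exc}")
            return
    else:
        var_n = variant

    length = provider.seq_length(variant.ac)
    niv = var_n.posedit.interval
    limit = length + 1 if variant.posedit.edit.kind == "ins" else length
    if not (1 <= niv.start.base and niv.end.base <= limit):
        report.add("e1", ERROR,
                   "the given coordinate is outside the bounds of the "
                   "reference sequence")
        return
    report.add("e1", VALID, "")

    stated = _stated_ref(variant.posedit.edit)
    if not intronic:
        if stated is not None and variant.posedit.edit.kind != "ins":
            actual = provider.get_seq(variant.ac, niv.start.base - 1,
                                      niv.end.base)
            _check_ref_against(report, stated, actual)
        else:
            report.add("e2", VALID, "")
        return

    # intronic: check against the genome when an alignment exists
    if record is None:
        report.add("e3", WARNING,
                   "intronic sequence cannot be validated or refuted "
                   "without a genomic alignment")
        return
    try:
        var_g = _mapper.n_to_g(var_n, record, provider)
    except (NotOnTranscriptError, HgvsError) as exc:
        report.add("e1", ERROR, f"intronic offset leaves the alignment: {exc}")
        return
    stated_g = _stated_ref(var_g.posedit.edit)
    if stated_g is not None and var_g.posedit.edit.kind != "ins":
        giv = var_g.posedit.interval
        actual = provider.get_seq(var_g.ac, giv.start.base - 1, giv.end.base)
        _check_ref_against(report, stated_g, actual)
    else:
        report.add("e2", VALID, "")


def _extrinsic_protein(variant: SequenceVariant, provider: DataProvider,
                       report: ValidationReport) -> None:
    try:
        length = provider.seq_length(variant.ac)
    except HgvsError:
        report.add("e2", WARNING,
                   "no protein sequence available; residues cannot be checked")
        return
    iv = variant.posedit.interval
    if iv.end.pos > length:
        report.add("e1", ERROR,
                   "the given residue is outside the bounds of the protein")
        return
    report.add("e1", VALID, "")
    seq = provider.get_seq(variant.ac)
    for pos in (iv.start, iv.end):
        if pos.aa not in ("X", seq[pos.pos - 1]):
            report.add("e2", ERROR,
                       f"stated residue {pos.aa} at {pos.pos} disagrees with "
                       f"protein sequence {seq[pos.pos - 1]}")
            return
    report.add("e2", VALID, "")


# --------------------------------------------------------------------------


def validate(variant: SequenceVariant, provider: DataProvider | None = None,
             strict: bool = False) -> ValidationReport:
    """Run intrinsic then extrinsic validation.

    Extrinsic validation is skipped when intrinsic validation found an ERROR
    (it could not be interpreted reliably anyway) or when no provider is
    given.  In strict mode any non-VALID overall level raises.
    """
    report = validate_intrinsic(variant)
    if provider is not None and report.overall != ERROR:
        report.extend(validate_extrinsic(variant, provider))
    if strict and report.overall != VALID:
        raise HgvsValidationError(
            f"{variant}: {report.overall}: "
            + "; ".join(report.messages() or ["criterion not satisfied"])
        )
    return report
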