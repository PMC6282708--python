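"""Configurable formatting of SequenceVariant objects back to HGVS strings.

Formatting only changes how a variant prints, never what is stored:
``max_ref_length`` suppresses long (or, at the default of 0, all) explicit
reference sequences on del/dup/inv edits; ``p_3_letter`` selects 1- or
3-letter amino acids; ``p_term_asterisk`` prints stop codons as ``*``
instead of ``Ter`` in 3-letter mode.
"""

from __future__ import annotations

from dataclasses import dataclass

from .edits import Edit
from .position import Anchor, BaseOffsetInterval, BaseOffsetPosition, ProteinInterval
from .sequences import AA3
from .variant import PosEdit, SequenceVariant


@dataclass(frozen=True)
class FormatterConfig:
    #: longest explicit del/dup/inv reference sequence to print; 0 suppresses
    #: all, None prints unconditionally
    max_ref_length: int | None = 0
    p_3_letter: bool = True
    p_term_asterisk: bool = False


DEFAULT_CONFIG = FormatterConfig()
VERBATIM_CONFIG = FormatterConfig(max_ref_length=None)


def format_variant(v: SequenceVariant, config: FormatterConfig = DEFAULT_CONFIG) -> str:
    if v.type == "p":
        body = _fmt_protein_posedit(v.posedit, config)
    else:
        body = _fmt_nuc_posedit(v.posedit, config)
    return f"{v.ac}:{v.type}.{body}"


# --------------------------------------------------------------------------
# nucleotide


def _fmt_pos(p: BaseOffsetPosition) -> str:
    out = "*" if p.anchor is Anchor.CDS_END else ""
    out += str(p.base)
    if p.offset:
        out += f"{p.offset:+d}"
    return out


def _fmt_interval(iv: BaseOffsetInterval) -> str:
    if iv.start == iv.end:
        return _fmt_pos(iv.start)
    return f"{_fmt_pos(iv.start)}_{_fmt_pos(iv.end)}"


def _ref_payload(ref: str | int | None, config: FormatterConfig) -> str:
    if ref is None:
        return ""
    if isinstance(ref, int):
        return str(ref)  # declared lengths always print
    if config.max_ref_length is None or len(ref) <= config.max_ref_length:
        return ref
    return ""


def _fmt_nuc_edit(edit: Edit, config: FormatterConfig) -> str:
    k = edit.kind
    if k == "sub":
        return f"{edit.ref}>{edit.alt}"
    if k == "del":
        return "del" + _ref_payload(edit.ref, config)
    if k == "ins":
        return "ins" + (edit.alt or "")
    if k == "delins":
        return "del" + _ref_payload(edit.ref, config) + "ins" + (edit.alt or "")
    if k == "dup":
        return "dup" + _ref_payload(edit.ref, config)
    if k == "inv":
        return "inv" + _ref_payload(edit.ref, config)
    if k == "identity":
        return "="
    if k == "repeat":
        return f"{edit.repeat_unit}[{edit.repeat_count}]"
    if k == "con":
        ac, type_, interval = edit.con_source
        src = _fmt_interval(interval)
        if type_:
            src = f"{type_}.{src}"
        if ac:
            src = f"{ac}:{src}"
        return "con" + src
    raise ValueError(f"cannot format nucleotide edit kind {k!r}")


def _fmt_nuc_posedit(pe: PosEdit, config: FormatterConfig) -> str:
    body = _fmt_interval(pe.interval) + _fmt_nuc_edit(pe.edit, config)
    return f"({body})" if pe.uncertain else body


# --------------------------------------------------------------------------
# protein


def _aa_fmt(aa: str, config: FormatterConfig) -> str:
    if aa == "*":
        if not config.p_3_letter or config.p_term_asterisk:
            return "*"
        return "Ter"
    return AA3[aa] if config.p_3_letter else aa


def _aas_fmt(seq: str | None, config: FormatterConfig) -> str:
    return "".join(_aa_fmt(aa, config) for aa in (seq or ""))


def _fmt_aa_pos(p, config: FormatterConfig) -> str:
    return f"{_aa_fmt(p.aa, config)}{p.pos}"


def _fmt_protein_posedit(pe: PosEdit, config: FormatterConfig) -> str:
    iv: ProteinInterval = pe.interval
    edit = pe.edit
    if edit.kind == "unknown":
        return "?"
    if iv.start == iv.end:
        loc = _fmt_aa_pos(iv.start, config)
    else:
        loc = f"{_fmt_aa_pos(iv.start, config)}_{_fmt_aa_pos(iv.end, config)}"
    k = edit.kind
    if k == "sub":
        body = f"{_fmt_aa_pos(iv.start, config)}{_aa_fmt(edit.alt, config)}"
    elif k == "identity":
        body = f"{_fmt_aa_pos(iv.start, config)}="
    elif k == "del":
        body = loc + "del"
    elif k == "dup":
        body = loc + "dup"
    elif k == "ins":
        body = loc + "ins" + _aas_fmt(edit.alt, config)
    elif k == "delins":
        body = loc + "delins" + _aas_fmt(edit.alt, config)
    elif k == "fs":
        term = "*" if (not config.p_3_letter or config.p_term_asterisk) else "Ter"
        body = f"{_fmt_aa_pos(iv.start, config)}{_aa_fmt(edit.alt, config)}fs"
        if edit.fs_term is not None:
            body += term + ("?" if edit.fs_term == -1 else str(edit.fs_term))
    elif k == "ext":
        term = "*" if (not config.p_3_letter or config.p_term_asterisk) else "Ter"
        body = f"{_fmt_aa_pos(iv.start, config)}{_aas_fmt(edit.alt, config)}ext"
        if edit.fs_term is not None:
            body += term + ("?" if edit.fs_term == -1 else str(edit.fs_term))
    else:
        raise ValueError(f"cannot format protein edit kind {k!r}")
    return f"({body})" if pe.uncertain else body
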