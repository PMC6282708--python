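"""HGVS string parsing.

The grammar is implemented as a hand-written recursive-descent parser with
one rule per variant kind, tried longest-match-first so that ``delins``
is recognized before ``del`` + ``ins`` and repeats (``CAG[7]``) are not
confused with compound alleles (``[...;...]``).

Two failure modes are deliberately distinct:

* :class:`HgvsSyntaxError` — the string is malformed (e.g. ``ins8``, which
  states a length where a sequence is required);
* :class:`UnsupportedVariantError` — the string may be legal HGVS that this
  package does not model: uncertain positions (``(?_17019)``), compound /
  mosaic / chimeric alleles, translocations, ISCN.
"""

from __future__ import annotations

import re

from .edits import Edit
from .exceptions import HgvsSyntaxError, UnsupportedVariantError
from .position import (
    AAPosition,
    Anchor,
    BaseOffsetInterval,
    BaseOffsetPosition,
    ProteinInterval,
)
from .sequences import AA1, AA3
from .variant import PosEdit, SequenceVariant

_NUC = "ACGTUN"
_NUC_RE = rf"[{_NUC}{_NUC.lower()}]"

_POS_G = re.compile(r"(\d+)")
_POS_N = re.compile(r"(\d+)([+-]\d+)?")
_POS_C = re.compile(r"(\*)?(-)?(\d+)([+-]\d+)?")

_AA_TOKEN = re.compile(r"(Ter|[A-Z][a-z]{2})|(\*|[A-Z])")


def parse(text: str) -> SequenceVariant:
    """Parse a single-variant HGVS description into a SequenceVariant."""
    for i, ch in enumerate(text):
        if ch.isspace():
            raise HgvsSyntaxError("whitespace is not allowed in HGVS strings", pos=i)
    colon = text.find(":")
    if colon <= 0:
        raise HgvsSyntaxError("expected '<accession>:<type>.<posedit>'", pos=0)
    ac = text[:colon]
    rest = text[colon + 1:]
    if len(rest) < 2 or rest[1] != ".":
        raise HgvsSyntaxError("expected coordinate type such as 'g.' or 'c.'",
                              pos=colon + 1)
    type_ = rest[0]
    posedit_text = rest[2:]
    base = colon + 3  # offset of posedit within the original string
    if type_ not in "gmncp":
        raise HgvsSyntaxError(f"unknown coordinate type {type_!r}", pos=colon + 1)
    if not posedit_text:
        raise HgvsSyntaxError("empty position/edit", pos=base)

    if type_ == "p":
        posedit = _parse_protein_posedit(posedit_text, base)
    else:
        _reject_unsupported(posedit_text, base)
        posedit = _parse_nuc_posedit(posedit_text, type_, base)
    return SequenceVariant(ac=ac, type=type_, posedit=posedit)


def _reject_unsupported(posedit: str, base: int) -> None:
    if posedit.startswith("[") or ";" in posedit:
        raise UnsupportedVariantError(
            "compound/mosaic/chimeric alleles are not supported"
        )
    for i, ch in enumerate(posedit):
        if ch in "(?)":
            raise UnsupportedVariantError(
                f"uncertain positions are not supported (at {base + i})"
            )


# --------------------------------------------------------------------------
# nucleotide posedits


def _parse_nuc_pos(text: str, type_: str, at: int) -> tuple[BaseOffsetPosition, int]:
    """Parse one position from the head of ``text``; return (pos, nchars)."""
    if type_ in ("g", "m"):
        m = _POS_G.match(text)
        if not m:
            raise HgvsSyntaxError("expected a genomic position", pos=at)
        return BaseOffsetPosition(int(m.group(1))), m.end()
    if type_ == "n":
        m = _POS_N.match(text)
        if not m:
            raise HgvsSyntaxError("expected a transcript position", pos=at)
        offset = int(m.group(2)) if m.group(2) else 0
        return BaseOffsetPosition(int(m.group(1)), offset), m.end()
    m = _POS_C.match(text)
    if not m or not m.group(3):
        raise HgvsSyntaxError("expected a CDS position", pos=at)
    star, minus, digits, off = m.groups()
    if star and minus:
        raise HgvsSyntaxError("a position cannot be both * and negative", pos=at)
    value = int(digits)
    if value == 0:
        raise HgvsSyntaxError("HGVS positions are 1-based; 0 is not a position", pos=at)
    anchor = Anchor.CDS_END if star else Anchor.CDS_START
    base_val = -value if minus else value
    offset = int(off) if off else 0
    return BaseOffsetPosition(base_val, offset, anchor), m.end()


def _parse_nuc_interval(text: str, type_: str, at: int) -> tuple[BaseOffsetInterval, int]:
    start, n = _parse_nuc_pos(text, type_, at)
    used = n
    if used < len(text) and text[used] == "_":
        end, n2 = _parse_nuc_pos(text[used + 1:], type_, at + used + 1)
        used += 1 + n2
    else:
        end = start
    return BaseOffsetInterval(start, end), used


def _seq_or_len(text: str) -> str | int | None:
    """Interpret an optional del/dup/inv payload: sequence, declared length,
    or nothing."""
    if not text:
        return None
    if text.isdigit():
        return int(text)
    if re.fullmatch(rf"{_NUC_RE}+", text):
        return text.upper()
    return "!"  # sentinel: malformed


def _parse_nuc_edit(text: str, at: int) -> Edit:
    if text == "=":
        return Edit("identity")

    m = re.fullmatch(rf"({_NUC_RE})>({_NUC_RE})", text)
    if m:
        return Edit("sub", ref=m.group(1).upper(), alt=m.group(2).upper())

    if text.startswith("inv"):
        payload = _seq_or_len(text[3:])
        if payload == "!":
            raise HgvsSyntaxError("malformed inversion payload", pos=at + 3)
        return Edit("inv", ref=payload)

    if text.startswith("con"):
        return Edit("con", con_source=_parse_con_source(text[3:], at + 3))

    if text.startswith("dup"):
        payload = _seq_or_len(text[3:])
        if payload == "!":
            raise HgvsSyntaxError("malformed duplication payload", pos=at + 3)
        return Edit("dup", ref=payload)

    if text.startswith("del"):
        rest = text[3:]
        ins_at = rest.find("ins")
        if ins_at >= 0:
            del_payload = _seq_or_len(rest[:ins_at])
            if del_payload == "!":
                raise HgvsSyntaxError("malformed deletion payload", pos=at + 3)
            alt = rest[ins_at + 3:]
            if not re.fullmatch(rf"{_NUC_RE}+", alt):
                # "delTins6": a declared alt length is not valid nomenclature
                raise HgvsSyntaxError(
                    "insertion requires an explicit sequence", pos=at + 3 + ins_at + 3
                )
            return Edit("delins", ref=del_payload, alt=alt.upper())
        payload = _seq_or_len(rest)
        if payload == "!":
            raise HgvsSyntaxError("malformed deletion payload", pos=at + 3)
        return Edit("del", ref=payload)

    if text.startswith("ins"):
        alt = text[3:]
        if not re.fullmatch(rf"{_NUC_RE}+", alt):
            # "ins8" is a syntactic error: insertions state the sequence
            raise HgvsSyntaxError("insertion requires an explicit sequence", pos=at + 3)
        return Edit("ins", alt=alt.upper())

    m = re.fullmatch(rf"({_NUC_RE}+)\[(\d+)\]", text)
    if m:
        return Edit("repeat", repeat_unit=m.group(1).upper(),
                    repeat_count=int(m.group(2)))

    raise HgvsSyntaxError(f"unrecognized edit {text!r}", pos=at)


def _parse_con_source(text: str, at: int) -> tuple:
    """Conversion source: ``[ac:][t.]interval`` on the same or another sequence."""
    ac = None
    type_ = None
    if ":" in text:
        ac, text = text.split(":", 1)
        at += len(ac) + 1
    if len(text) >= 2 and text[0] in "gmnc" and text[1] == ".":
        type_ = text[0]
        text = text[2:]
        at += 2
    interval, used = _parse_nuc_interval(text, type_ or "g", at)
    if used != len(text):
        raise HgvsSyntaxError("trailing characters after conversion source",
                              pos=at + used)
    return (ac, type_, interval)


def _parse_nuc_posedit(text: str, type_: str, at: int) -> PosEdit:
    interval, used = _parse_nuc_interval(text, type_, at)
    edit_text = text[used:]
    if not edit_text:
        raise HgvsSyntaxError("missing edit after position", pos=at + used)
    edit = _parse_nuc_edit(edit_text, at + used)
    return PosEdit(interval=interval, edit=edit)


# --------------------------------------------------------------------------
# protein posedits


def _parse_aa(text: str, at: int) -> tuple[str, int]:
    """One amino-acid token (1- or 3-letter, Ter or *) -> (1-letter, nchars)."""
    m = _AA_TOKEN.match(text)
    if not m:
        raise HgvsSyntaxError("expected an amino-acid token", pos=at)
    if m.group(1):
        if m.group(1) not in AA1:
            raise HgvsSyntaxError(f"unknown amino acid {m.group(1)!r}", pos=at)
        return AA1[m.group(1)], m.end()
    one = m.group(2)
    if one != "*" and one not in AA3:
        raise HgvsSyntaxError(f"unknown amino acid {one!r}", pos=at)
    return one, m.end()


def _parse_aa_seq(text: str, at: int) -> str:
    out = []
    i = 0
    while i < len(text):
        aa, n = _parse_aa(text[i:], at + i)
        out.append(aa)
        i += n
    if not out:
        raise HgvsSyntaxError("expected an amino-acid sequence", pos=at)
    return "".join(out)


def _parse_aa_pos(text: str, at: int) -> tuple[AAPosition, int]:
    aa, n = _parse_aa(text, at)
    m = re.match(r"\d+", text[n:])
    if not m:
        raise HgvsSyntaxError("expected a residue number", pos=at + n)
    return AAPosition(int(m.group(0)), aa), n + m.end()


def _parse_protein_posedit(text: str, at: int) -> PosEdit:
    uncertain = False
    if text == "?":
        return PosEdit(ProteinInterval(AAPosition(1, "X")), Edit("unknown"))
    if text.startswith("(") and text.endswith(")"):
        uncertain = True
        text = text[1:-1]
        at += 1
    if "?" in text or "(" in text or ")" in text:
        raise UnsupportedVariantError("uncertain protein descriptions are not supported")
    if ";" in text or text.startswith("["):
        raise UnsupportedVariantError("compound protein alleles are not supported")

    start, used = _parse_aa_pos(text, at)
    if used < len(text) and text[used] == "_":
        end, n2 = _parse_aa_pos(text[used + 1:], at + used + 1)
        used += 1 + n2
    else:
        end = start
    interval = ProteinInterval(start, end)
    rest = text[used:]
    rat = at + used
    edit = _parse_protein_edit(rest, interval, rat)
    return PosEdit(interval=interval, edit=edit, uncertain=uncertain)


def _parse_protein_edit(rest: str, interval: ProteinInterval, at: int) -> Edit:
    start = interval.start
    if rest == "=":
        return Edit("identity", ref=start.aa, alt=start.aa)
    if rest == "del":
        return Edit("del", ref=None)
    if rest == "dup":
        return Edit("dup", ref=None)
    if rest.startswith("delins"):
        return Edit("delins", alt=_parse_aa_seq(rest[6:], at + 6))
    if rest.startswith("ins"):
        return Edit("ins", alt=_parse_aa_seq(rest[3:], at + 3))

    m = re.fullmatch(r"(.+?)fs(?:(?:Ter|\*)(\d+|\?)?)?", rest)
    if m:
        alt = _parse_aa_seq(m.group(1), at)
        if len(alt) != 1:
            raise HgvsSyntaxError("frameshift states one new residue", pos=at)
        term = m.group(2)
        fs_term = None if term is None else (-1 if term == "?" else int(term))
        return Edit("fs", ref=start.aa, alt=alt, fs_term=fs_term)

    m = re.fullmatch(r"(.+?)ext(?:Ter|\*)?(\d+|\?)?", rest)
    if m:
        alt = _parse_aa_seq(m.group(1), at)
        term = m.group(2)
        fs_term = None if term is None else (-1 if term == "?" else int(term))
        return Edit("ext", ref=start.aa, alt=alt, fs_term=fs_term)

    # plain substitution: exactly one amino acid remains
    alt = _parse_aa_seq(rest, at)
    if len(alt) != 1:
        raise HgvsSyntaxError("substitution states one new residue", pos=at)
    return Edit("sub", ref=start.aa, alt=alt)
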