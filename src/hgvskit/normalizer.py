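"""Variant normalization: canonical HGVS form.

A variant has many syntactically valid spellings (on ``GCTTTA``, the change
to ``GCTTA`` can be written ``3delT``, ``4delT``, ``5delT``,
``3_5delTTTinsTT``, or ``3_4delTTinsT``).  Normalization converges them to
one canonical form by

1. trimming bases shared by the reference and alternate alleles,
2. shifting the remaining edit as far 3' as an equivalent placement exists
   (using a dynamic extension window over provider reads, so long
   homopolymer runs do not require unbounded fetches), and
3. rewriting the edit as the highest-priority kind that represents it:
   substitution > deletion > inversion > duplication > insertion >
   deletion-insertion.  Repeats and conversions pass through unchanged.

For transcript (c./n.) variants the shift never crosses an exon-intron
boundary unless ``cross_boundaries`` is set, because a placement that is 3'
on the transcript may describe different genomic bases once introns are
restored.  Intronic variants are normalized in genomic context when an
alignment is available, and otherwise returned unchanged with a notice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from . import mapper as _mapper
from .edits import Edit
from .exceptions import HgvsError, HgvsValidationError, ReferenceDisagreementError
from .position import BaseOffsetInterval, BaseOffsetPosition
from .provider import DataProvider
from .sequences import reverse_complement
from .variant import PosEdit, SequenceVariant

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalizerConfig:
    shift_direction: str = "3p"  # "3p" (HGVS canonical) or "5p" (VCF-style)
    cross_boundaries: bool = False
    window_size: int = 20  # initial dynamic-window extent, bases

    def __post_init__(self) -> None:
        if self.shift_direction not in ("3p", "5p"):
            raise HgvsError("shift_direction must be '3p' or '5p'")
        if self.window_size < 1:
            raise HgvsError("window_size must be >= 1")


DEFAULT_CONFIG = NormalizerConfig()


# --------------------------------------------------------------------------
# the three elementary steps (1-based inclusive intervals at the interface)


def trim_alleles(ref: str, alt: str, interval: tuple[int, int],
                 ) -> tuple[str, str, tuple[int, int]]:
    """Remove bases common to both alleles and adjust the interval.

    Returns ``(ref', alt', interval')`` where at most one allele is empty;
    when the trimmed change is a pure insertion the interval names the two
    flanking bases.  Trimming both alleles to nothing returns two empty
    strings with the original interval (an identity).
    """
    s, e = interval[0] - 1, interval[1]  # interbase
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        s += 1
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
        e -= 1
    if not ref and not alt:
        return "", "", interval
    if not ref:  # pure insertion between s and s+1 (1-based flanks)
        return "", alt, (s, s + 1)
    return ref, alt, (s + 1, e)


class _Window:
    """Windowed base access over a provider read, doubling on exhaustion."""

    def __init__(self, fetch, anchor: int, limit_lo: int, limit_hi: int,
                 size: int):
        self._fetch = fetch
        self._lo = limit_lo
        self._hi = limit_hi
        self._size = size
        self._buf_start = anchor
        self._buf = ""

    def base(self, i: int) -> str | None:
        if not (self._lo <= i < self._hi):
            return None
        while not (self._buf_start <= i < self._buf_start + len(self._buf)):
            # extend (and re-anchor if needed), doubling the window
            want = max(self._size, 2 * len(self._buf))
            lo = min(self._buf_start, i)
            hi = min(max(lo + want, i + 1), self._hi)
            lo = max(lo, self._lo)
            self._buf = self._fetch(lo, hi)
            self._buf_start = lo
            self._size = want
        return self._buf[i - self._buf_start]


def shift_3prime(ref: str, alt: str, interval: tuple[int, int], fetch,
                 limit_lo: int = 0, limit_hi: int | None = None,
                 window_size: int = 20, direction: str = "3p",
                 ) -> tuple[str, str, tuple[int, int]]:
    """Move a trimmed pure insertion or deletion to its most-3' equivalent
    placement (or most-5' with ``direction='5p'``).

    ``fetch(start_i, end_i)`` returns reference bases in interbase
    coordinates; ``limit_lo``/``limit_hi`` bound the shift (sequence ends,
    and exon boundaries for transcript variants).  Anything that is not a
    pure insertion or deletion is returned unchanged: after trimming, an
    edit with bases on both sides has no equivalent placements.
    """
    if bool(ref) == bool(alt):
        return ref, alt, interval
    is_del = bool(ref)
    allele = ref or alt
    pos = interval[0] - 1 if is_del else interval[0]  # interbase anchor
    if limit_hi is None:
        raise HgvsError("shift requires an explicit 3' limit")
    win = _Window(fetch, pos, limit_lo, limit_hi, window_size)
    if direction == "3p":
        while True:
            nxt = pos + (len(allele) if is_del else 0)
            b = win.base(nxt)
            if b is None or b != allele[0]:
                break
            allele = allele[1:] + b
            pos += 1
    else:
        while True:
            prv = pos - 1
            b = win.base(prv)
            if b is None or b != allele[-1]:
                break
            allele = b + allele[:-1]
            pos -= 1
    if is_del:
        return allele, "", (pos + 1, pos + len(allele))
    return "", allele, (pos, pos + 1)


def rewrite_edit(ref: str, alt: str, interval: tuple[int, int],
                 preceding_seq: str) -> tuple[Edit, tuple[int, int]]:
    """Re-express a trimmed, shifted change as the highest-priority edit
    kind, returning the edit and its (possibly moved) 1-based interval.

    ``preceding_seq`` holds the reference bases immediately 5' of the
    interval (at least ``len(alt)`` of them when available) and is consulted
    only for the insertion→duplication rewrite.
    """
    if not ref and not alt:
        return Edit("identity"), interval
    if len(ref) == 1 and len(alt) == 1:
        return Edit("sub", ref=ref, alt=alt), interval
    if not alt:
        return Edit("del", ref=ref), interval
    if not ref:
        if len(preceding_seq) >= len(alt) and preceding_seq[-len(alt):] == alt:
            # insertion of the immediately preceding bases: a duplication
            pos = interval[0]  # 5' flank of the insertion point
            return Edit("dup", ref=alt), (pos - len(alt) + 1, pos)
        return Edit("ins", alt=alt), interval
    if len(ref) > 1 and alt == reverse_complement(ref):
        return Edit("inv", ref=ref), interval
    return Edit("delins", ref=ref, alt=alt), interval


# --------------------------------------------------------------------------
# the full pipeline


class Normalizer:
    """Composes trim → shift → rewrite against a data provider."""

    def __init__(self, provider: DataProvider,
                 config: NormalizerConfig = DEFAULT_CONFIG,
                 validate_first: bool = True):
        self.provider = provider
        self.config = config
        self.validate_first = validate_first

    def normalize(self, variant: SequenceVariant) -> SequenceVariant:
        if variant.type == "p":
            return variant
        edit = variant.posedit.edit
        if edit.kind in ("con", "repeat"):
            logger.info("normalization of %s edits is not supported; "
                        "returning %s unchanged", edit.kind, variant)
            return variant
        if self.validate_first:
            from .validation import validate  # deferred: validation uses mapper

            report = validate(variant, self.provider)
            if report.overall == "ERROR":
                raise HgvsValidationError(
                    f"cannot normalize invalid variant {variant}: "
                    + "; ".join(m for _, lvl, m in report.outcomes if lvl == "ERROR")
                )

        iv = variant.posedit.interval
        if variant.type in ("c", "n") and (iv.start.offset or iv.end.offset):
            return self._normalize_intronic(variant)
        if variant.type == "c":
            record = self.provider.get_transcript(variant.ac)
            var_n = _mapper.c_to_n(variant, record)
            out = self._normalize_plain(var_n)
            return _mapper.n_to_c(out, record)
        return self._normalize_plain(variant)

    # -- helpers -----------------------------------------------------------
    def _normalize_intronic(self, variant: SequenceVariant) -> SequenceVariant:
        try:
            record = self.provider.get_transcript(variant.ac)
            record.placement_for()
        except HgvsError:
            logger.info("no genomic context for %s; intronic variant "
                        "returned unchanged", variant.ac)
            return variant
        var_n = (_mapper.c_to_n(variant, record) if variant.type == "c"
                 else variant)
        var_g = _mapper.n_to_g(var_n, record, self.provider)
        norm_g = self._normalize_plain(var_g)
        back_n = _mapper.g_to_n(norm_g, record, self.provider)
        if variant.type == "c":
            return _mapper.n_to_c(back_n, record)
        return back_n

    def _shift_limits(self, variant: SequenceVariant, s: int, e: int,
                      ) -> tuple[int, int]:
        seq_len = self.provider.seq_length(variant.ac)
        if variant.type in ("g", "m") or self.config.cross_boundaries:
            return 0, seq_len
        try:
            record = self.provider.get_transcript(variant.ac)
        except HgvsError:
            return 0, seq_len  # no exon structure known: no boundaries to respect
        for exon in record.placements[0].exons:
            if exon.tx_start <= s and e <= exon.tx_end:
                return exon.tx_start, exon.tx_end
        return s, e  # interval straddles a junction: do not shift

    def _normalize_plain(self, variant: SequenceVariant) -> SequenceVariant:
        """Normalize a g./m. or plain-coordinate n. variant."""
        pe = variant.posedit
        edit = pe.edit
        if edit.kind == "ins":
            s = e = pe.interval.start.base
        else:
            s, e = pe.interval.start.base - 1, pe.interval.end.base

        ref = self.provider.get_seq(variant.ac, s, e)
        if isinstance(edit.ref, str) and edit.ref and edit.ref != ref:
            raise ReferenceDisagreementError(
                f"stated reference {edit.ref!r} != sequence {ref!r} in {variant}"
            )
        alt = {
            "sub": lambda: edit.alt,
            "del": lambda: "",
            "delins": lambda: edit.alt,
            "ins": lambda: edit.alt,
            "dup": lambda: ref + ref,
            "inv": lambda: reverse_complement(ref),
            "identity": lambda: ref,
        }[edit.kind]()

        ref_t, alt_t, interval = trim_alleles(ref, alt, (s + 1, e))
        if not ref_t and not alt_t:
            new_pe = PosEdit(pe.interval, Edit("identity", ref=ref, alt=ref))
            return variant.with_posedit(new_pe)

        s_t = interval[0] - 1 if ref_t else interval[0]
        e_t = interval[1] if ref_t else interval[0]
        lo, hi = self._shift_limits(variant, s_t, e_t)
        fetch = lambda a, b: self.provider.get_seq(variant.ac, a, b)
        ref_s, alt_s, interval = shift_3prime(
            ref_t, alt_t, interval, fetch, lo, hi,
            self.config.window_size, self.config.shift_direction,
        )

        ins_point = interval[0] if not ref_s else interval[0] - 1
        pre_lo = max(lo, ins_point - max(len(alt_s), 1))
        preceding = fetch(pre_lo, ins_point) if ins_point > pre_lo else ""
        new_edit, interval = rewrite_edit(ref_s, alt_s, interval, preceding)

        new_iv = BaseOffsetInterval(
            BaseOffsetPosition(interval[0]), BaseOffsetPosition(interval[1])
        )
        if new_edit.kind == "ins" and new_iv.end.base != new_iv.start.base + 1:
            raise HgvsError("internal error: malformed insertion interval")
        return variant.with_posedit(PosEdit(new_iv, new_edit))


def normalize(variant: SequenceVariant, provider: DataProvider,
              config: NormalizerConfig = DEFAULT_CONFIG,
              validate_first: bool = True) -> SequenceVariant:
    """Normalize ``variant`` against ``provider`` (see class docstring)."""
    return Normalizer(provider, config, validate_first).normalize(variant)
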