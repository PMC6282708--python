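"""Gap-aware projection of variants between transcript and genome.

Coordinates
-----------
All arithmetic is in interbase coordinates.  Within one exon, alignment
segments (M/X/I/D) relate transcript offsets to "alignment-space" genomic
offsets that increase in the transcript's 5'→3' direction; for minus-strand
transcripts these are reflected into absolute (plus-strand) genomic
coordinates at the edges of each computation.  Introns are not alignment
segments — intronic positions are expressed as exon-edge bases plus signed
offsets, choosing the closest exon edge (ties go to the upstream exon, i.e.
a ``+`` offset).

Gap policy
----------
A variant interval that intersects an alignment gap is widened to the
smallest interval whose endpoints are unambiguous on both sequences: an
endpoint inside transcript-only bases (I) is moved to the I-segment
boundary, an endpoint inside genome-only bases (D) is moved to the
D-segment boundary, and endpoints that merely abut a gap exclude it.  The
projected alternate allele is then recomputed from the full edited source
sequence over the widened interval, so the projected variant is
allele-equivalent to its source by construction, including for variants
that fall within, exactly cover, partially cover, or span alignment gaps.
Reference bases for the projected variant are always taken from the target
sequence (reference replacement), so transcript-genome substitution
discrepancies are resolved in favour of the target.
"""

from __future__ import annotations

from dataclasses import dataclass

from .edits import Edit, edit_alleles
from .exceptions import (
    BoundsError,
    HgvsError,
    NoCdsError,
    NotOnTranscriptError,
)
from .position import Anchor, BaseOffsetInterval, BaseOffsetPosition
from .provider import DataProvider, Placement, TranscriptRecord
from .sequences import reverse_complement
from .variant import PosEdit, SequenceVariant


def _classify(ref: str, alt: str) -> str:
    """Pick the natural edit kind for a raw ref→alt change (pre-normalization)."""
    if ref == alt:
        return "identity"
    if len(ref) == 1 and len(alt) == 1:
        return "sub"
    if not ref:
        return "ins"
    if not alt:
        return "del"
    return "delins"


def _build_posedit(start_i: int, end_i: int, ref: str, alt: str) -> PosEdit:
    """PosEdit from interbase interval and alleles (nucleotide, no offsets)."""
    kind = _classify(ref, alt)
    if kind == "ins":
        interval = BaseOffsetInterval(
            BaseOffsetPosition(start_i), BaseOffsetPosition(start_i + 1)
        )
        return PosEdit(interval, Edit("ins", alt=alt))
    interval = BaseOffsetInterval(
        BaseOffsetPosition(start_i + 1), BaseOffsetPosition(end_i)
    )
    if kind == "sub":
        return PosEdit(interval, Edit("sub", ref=ref, alt=alt))
    if kind == "del":
        return PosEdit(interval, Edit("del", ref=ref))
    if kind == "identity":
        return PosEdit(interval, Edit("identity", ref=ref, alt=alt))
    return PosEdit(interval, Edit("delins", ref=ref, alt=alt))


@dataclass(frozen=True)
class _Seg:
    op: str
    tx_lo: int  # transcript interbase, absolute on the transcript
    tx_hi: int
    a_lo: int  # alignment-space genomic offset within the exon
    a_hi: int


class TranscriptMapper:
    """Coordinate projection for one transcript on one genomic placement."""

    def __init__(self, record: TranscriptRecord, placement: Placement):
        self.record = record
        self.placement = placement
        self.strand = placement.strand
        self.tx_len = record.placements[0].exons[-1].tx_end
        self._exon_segs: list[list[_Seg]] = []
        for exon in placement.exons:
            segs = []
            t, a = exon.tx_start, 0
            for seg in exon.segments:
                segs.append(_Seg(seg.op, t, t + seg.tx_len, a, a + seg.g_len))
                t += seg.tx_len
                a += seg.g_len
            self._exon_segs.append(segs)

    # -- exon lookup -------------------------------------------------------
    def _exon_index_for_tx(self, p: int, side: str) -> int:
        exons = self.placement.exons
        for i, exon in enumerate(exons):
            if exon.tx_start < p < exon.tx_end:
                return i
            if p == exon.tx_start and (side == "start" or i == 0):
                return i
            if p == exon.tx_end and (side == "end" or i == len(exons) - 1):
                return i
        raise BoundsError(
            f"transcript position {p} outside 0..{self.tx_len} of {self.record.tx_ac}"
        )

    # -- point projections -------------------------------------------------
    def _tx_point_to_aln(self, p: int, side: str) -> tuple[int, int]:
        """Map a transcript interbase point to (exon index, alignment offset).

        At a point adjacent to genome-only (D) bases the mapping is a range;
        interval starts take the 3' side (excluding the D bases) and interval
        ends the 5' side, so abutting gaps are never swallowed.
        """
        i = self._exon_index_for_tx(p, side)
        a_min = None
        a_max = None
        for seg in self._exon_segs[i]:
            if seg.tx_lo <= p <= seg.tx_hi and seg.op != "D":
                a = seg.a_lo + (p - seg.tx_lo) if seg.op in ("M", "X") else seg.a_lo
                if seg.op == "I" and p == seg.tx_hi:
                    a = seg.a_hi  # zero genomic width; lo == hi
                a_min = a if a_min is None else min(a_min, a)
                a_max = a if a_max is None else max(a_max, a)
            elif seg.tx_lo == p == seg.tx_hi and seg.op == "D":
                a_min = seg.a_lo if a_min is None else min(a_min, seg.a_lo)
                a_max = seg.a_hi if a_max is None else max(a_max, seg.a_hi)
        if a_min is None:
            raise BoundsError(f"cannot align transcript point {p}")
        return i, (a_max if side == "start" else a_min)

    def _aln_to_abs(self, exon_index: int, a: int) -> int:
        exon = self.placement.exons[exon_index]
        if self.strand == +1:
            return exon.g_start + a
        return exon.g_end - a

    def _abs_point_to_tx(self, p_abs: int, side: str) -> tuple[int, int]:
        """Absolute genomic interbase point -> (exon index, transcript point).

        Endpoints inside genome-only (D) bases widen to the D boundary;
        endpoints abutting transcript-only (I) bases exclude them.
        """
        for i, exon in enumerate(self.placement.exons):
            if not (exon.g_start <= p_abs <= exon.g_end):
                continue
            a = (p_abs - exon.g_start) if self.strand == +1 else (exon.g_end - p_abs)
            t_min = None
            t_max = None
            for seg in self._exon_segs[i]:
                if seg.a_lo <= a <= seg.a_hi and seg.op != "I":
                    if seg.op in ("M", "X"):
                        t = seg.tx_lo + (a - seg.a_lo)
                    else:  # D: zero transcript width
                        t = seg.tx_lo
                    t_min = t if t_min is None else min(t_min, t)
                    t_max = t if t_max is None else max(t_max, t)
                elif seg.a_lo == a == seg.a_hi and seg.op == "I":
                    t_min = seg.tx_lo if t_min is None else min(t_min, seg.tx_lo)
                    t_max = seg.tx_hi if t_max is None else max(t_max, seg.tx_hi)
            if t_min is None:
                continue
            # D interior: widen outward; I adjacency: exclude the I bases
            for seg in self._exon_segs[i]:
                if seg.op == "D" and seg.a_lo < a < seg.a_hi:
                    return i, seg.tx_lo
            return i, (t_max if side == "start" else t_min)
        raise NotOnTranscriptError(
            f"genomic point {p_abs} is not exonic on {self.record.tx_ac}"
        )

    # -- widening ----------------------------------------------------------
    def _widen_tx(self, s: int, e: int) -> tuple[int, int]:
        """Extend a transcript interbase interval so it never ends inside
        transcript-only (I) bases; zero-width intervals inside an I segment
        widen to the whole segment."""
        for segs in self._exon_segs:
            for seg in segs:
                if seg.op != "I":
                    continue
                if s == e and seg.tx_lo <= s <= seg.tx_hi:
                    # an insertion point at (or inside) the gap projects to
                    # the gap's genomic point, where inserted content
                    # supersedes the gap bases — so the alt must carry them
                    return seg.tx_lo, seg.tx_hi
                if seg.tx_lo < s < seg.tx_hi:
                    s = seg.tx_lo
                if seg.tx_lo < e < seg.tx_hi:
                    e = seg.tx_hi
        return s, e

    def _widen_abs_for_ins(self, p: int) -> tuple[int, int] | None:
        """If an absolute genomic point sits strictly inside genome-only (D)
        bases, return the absolute span of the whole D segment."""
        for i, exon in enumerate(self.placement.exons):
            if not (exon.g_start <= p <= exon.g_end):
                continue
            a = (p - exon.g_start) if self.strand == +1 else (exon.g_end - p)
            for seg in self._exon_segs[i]:
                if seg.op == "D" and seg.a_lo < a < seg.a_hi:
                    lo = self._aln_to_abs(i, seg.a_lo)
                    hi = self._aln_to_abs(i, seg.a_hi)
                    return min(lo, hi), max(lo, hi)
        return None

    def _tx_span_at_I_point(self, p: int) -> tuple[int, int] | None:
        """If an absolute genomic point is the (zero-width) location of
        transcript-only (I) bases, return their transcript span."""
        for i, exon in enumerate(self.placement.exons):
            if not (exon.g_start <= p <= exon.g_end):
                continue
            a = (p - exon.g_start) if self.strand == +1 else (exon.g_end - p)
            for seg in self._exon_segs[i]:
                if seg.op == "I" and seg.a_lo == a == seg.a_hi:
                    return seg.tx_lo, seg.tx_hi
        return None

    # -- per-base maps (intronic support) -----------------------------------
    def _g_base_of_tx_base(self, b: int) -> int:
        """Exonic transcript base (1-based) -> absolute genomic base (1-based)."""
        i, a = self._tx_point_to_aln(b - 1, "start")
        exon = self.placement.exons[i]
        if self.strand == +1:
            return exon.g_start + a + 1
        return exon.g_end - a

    def _tx_base_of_g_base(self, p: int) -> BaseOffsetPosition:
        """Absolute genomic base (1-based) -> transcript position, intronic
        positions as exon-edge base + closest signed offset (ties upstream)."""
        exons = self.placement.exons
        for i, exon in enumerate(exons):
            if not (exon.g_start <= p - 1 and p <= exon.g_end):
                continue  # the base [p-1, p) is not inside this exon
            a = (p - 1 - exon.g_start) if self.strand == +1 else (exon.g_end - p)
            for seg in self._exon_segs[i]:
                if seg.op in ("M", "X") and seg.a_lo <= a < seg.a_hi:
                    return BaseOffsetPosition(seg.tx_lo + (a - seg.a_lo) + 1)
                if seg.op == "D" and seg.a_lo <= a < seg.a_hi:
                    # genome-only base: report the transcript base 3' of
                    # the gap (the gap has no transcript image of its own)
                    return BaseOffsetPosition(seg.tx_lo + 1)
        for i in range(len(exons) - 1):
            up, down = exons[i], exons[i + 1]
            if self.strand == +1:
                lo, hi = up.g_end, down.g_start  # intron interbase span
                if not (lo < p <= hi):
                    continue
                k_up = p - lo
                k_down = hi - p + 1
            else:
                lo, hi = down.g_end, up.g_start
                if not (lo < p <= hi):
                    continue
                k_up = hi - p + 1
                k_down = p - lo
            if k_up <= k_down:
                return BaseOffsetPosition(up.tx_end, +k_up)
            return BaseOffsetPosition(down.tx_start + 1, -k_down)
        raise NotOnTranscriptError(
            f"genomic base {p} is outside the span of {self.record.tx_ac}"
        )

    def _g_base_of_offset_pos(self, pos: BaseOffsetPosition) -> int:
        """Transcript position (possibly intronic) -> absolute genomic base."""
        if not (1 <= pos.base <= self.tx_len):
            raise BoundsError(
                f"position {pos.base} outside 1..{self.tx_len} of {self.record.tx_ac}"
            )
        gb = self._g_base_of_tx_base(pos.base)
        return gb + pos.offset * self.strand

    # -- interval projections ----------------------------------------------
    def _interval_abs(self, S: int, E: int) -> tuple[int, int]:
        i1, a1 = self._tx_point_to_aln(S, "start")
        i2, a2 = self._tx_point_to_aln(E, "end")
        g1 = self._aln_to_abs(i1, a1)
        g2 = self._aln_to_abs(i2, a2)
        return min(g1, g2), max(g1, g2)

    def _flush_I_side(self, S: int, E: int, gs: int, ge: int) -> str | None:
        """Detect a transcript-only (I) gap inside [S,E) whose genomic gap
        point sits flush at the region edge — the edited region must cover
        it strictly for the gap bases to be superseded on re-splicing."""
        start_abs, end_abs = (gs, ge) if self.strand == +1 else (ge, gs)
        for i, segs in enumerate(self._exon_segs):
            for seg in segs:
                if seg.op != "I" or not (S <= seg.tx_lo and seg.tx_hi <= E):
                    continue
                p = self._aln_to_abs(i, seg.a_lo)
                if p == start_abs:
                    return "start"
                if p == end_abs:
                    return "end"
        return None

    def n_interval_to_g(self, s: int, e: int) -> tuple[int, int, int, int]:
        """Exonic transcript interbase [s,e) -> (gs, ge, S, E): the absolute
        genomic interval and the widened transcript interval it represents.

        Widening covers whole transcript-only (I) segments and, when such a
        segment would sit flush at the genomic region edge, extends by one
        more transcript base so the gap point lies strictly inside."""
        if not (0 <= s <= e <= self.tx_len):
            raise BoundsError(
                f"transcript interval [{s},{e}) outside 0..{self.tx_len} "
                f"of {self.record.tx_ac}"
            )
        S, E = self._widen_tx(s, e)
        if S == E:
            i, a = self._tx_point_to_aln(S, "end")
            g = self._aln_to_abs(i, a)
            return g, g, S, E
        for _ in range(64):
            gs, ge = self._interval_abs(S, E)
            if gs == ge:
                break  # interval is entirely transcript-only bases
            side = self._flush_I_side(S, E, gs, ge)
            if side == "start" and S > 0:
                S -= 1
            elif side == "end" and E < self.tx_len:
                E += 1
            else:
                break
            S, E = self._widen_tx(S, E)
        return gs, ge, S, E


# ---------------------------------------------------------------------------
# variant-level projections


def _nuc_interbase(pe: PosEdit) -> tuple[int, int]:
    """Interbase interval of a plain (offset-free) nucleotide posedit; for
    insertions, the zero-width insertion point between the stated flanks."""
    iv = pe.interval
    if pe.edit.kind == "ins":
        return iv.start.base, iv.start.base
    return iv.start.base - 1, iv.end.base


def n_to_g(variant_n: SequenceVariant, record: TranscriptRecord,
           provider: DataProvider, placement: Placement | None = None,
           ) -> SequenceVariant:
    """Project an n. variant onto its aligned genomic sequence.

    Exonic variants are projected through the gapped alignment with allele
    recomputation (see module docstring); intronic endpoints are projected
    by exon-edge-plus-offset arithmetic.  Positions beyond the transcript
    raise :class:`BoundsError` — the mapper never extrapolates.
    """
    if variant_n.type != "n":
        raise HgvsError(f"expected an n. variant, got {variant_n.type}.")
    placement = placement or record.placement_for()
    tm = TranscriptMapper(record, placement)
    pe = variant_n.posedit
    iv = pe.interval
    edit = pe.edit

    if edit.kind in ("con", "repeat"):
        raise HgvsError(f"projection of {edit.kind} edits is not supported")

    for pos in (iv.start, iv.end):
        if not (1 <= pos.base <= tm.tx_len):
            raise BoundsError(
                f"position {pos.base} outside 1..{tm.tx_len} of {record.tx_ac}"
            )

    if iv.start.offset == 0 and iv.end.offset == 0:
        return _n_to_g_exonic(variant_n, tm, provider, placement)
    return _n_to_g_by_base(variant_n, tm, provider, placement)


def _n_to_g_exonic(variant_n: SequenceVariant, tm: TranscriptMapper,
                   provider: DataProvider, placement: Placement) -> SequenceVariant:
    pe = variant_n.posedit
    s, e = _nuc_interbase(pe)
    tx_seq = provider.get_seq(variant_n.ac)
    if pe.edit.kind == "ins":
        ref, alt = "", pe.edit.alt or ""
    else:
        ref, alt = edit_alleles(tx_seq, s, e, pe.edit)
    gs, ge, S, E = tm.n_interval_to_g(s, e)
    alt_w = tx_seq[S:s] + alt + tx_seq[e:E]
    if tm.strand == -1:
        alt_w = reverse_complement(alt_w)
    g_ref = provider.get_seq(placement.g_ac, gs, ge)
    if gs == ge and not alt_w:
        # edit vanished on the genome (e.g. deletion of transcript-only bases)
        posedit = _build_posedit(gs, gs + 1,
                                 provider.get_seq(placement.g_ac, gs, gs + 1),
                                 provider.get_seq(placement.g_ac, gs, gs + 1))
        return SequenceVariant(placement.g_ac, "g", posedit)
    posedit = _build_posedit(gs, ge, g_ref, alt_w)
    return SequenceVariant(placement.g_ac, "g", posedit)


def _n_to_g_by_base(variant_n: SequenceVariant, tm: TranscriptMapper,
                    provider: DataProvider, placement: Placement) -> SequenceVariant:
    pe = variant_n.posedit
    iv = pe.interval
    p1 = tm._g_base_of_offset_pos(iv.start)
    p2 = tm._g_base_of_offset_pos(iv.end)
    lo, hi = min(p1, p2), max(p1, p2)
    edit = pe.edit
    ref = edit.ref
    alt = edit.alt
    if tm.strand == -1:
        if isinstance(ref, str) and ref:
            ref = reverse_complement(ref)
        if alt:
            alt = reverse_complement(alt)
    new_edit = Edit(edit.kind, ref=ref, alt=alt,
                    repeat_unit=edit.repeat_unit, repeat_count=edit.repeat_count)
    interval = BaseOffsetInterval(BaseOffsetPosition(lo), BaseOffsetPosition(hi))
    return SequenceVariant(placement.g_ac, "g", PosEdit(interval, new_edit))


def g_to_n(variant_g: SequenceVariant, record: TranscriptRecord,
           provider: DataProvider, placement: Placement | None = None,
           ) -> SequenceVariant:
    """Project a g. variant onto a transcript.

    Fully exonic intervals go through the gapped alignment with allele
    recomputation; intronic endpoints become exon-edge bases with the
    closest signed offset (ties to the upstream exon's ``+`` offset).
    """
    if variant_g.type not in ("g", "m"):
        raise HgvsError(f"expected a g. variant, got {variant_g.type}.")
    placement = placement or record.placement_for(g_ac=variant_g.ac)
    tm = TranscriptMapper(record, placement)
    pe = variant_g.posedit
    gs, ge = _nuc_interbase(pe)

    lo, hi = placement.g_span
    if gs < lo or ge > hi:
        raise NotOnTranscriptError(
            f"genomic interval [{gs},{ge}) not within {record.tx_ac} span [{lo},{hi})"
        )

    if pe.edit.kind in ("con", "repeat"):
        raise HgvsError(f"projection of {pe.edit.kind} edits is not supported")

    exonic = _is_exonic_span(tm, gs, ge)
    if exonic:
        return _g_to_n_exonic(variant_g, tm, provider, record)
    return _g_to_n_by_base(variant_g, tm, record)


def _is_exonic_span(tm: TranscriptMapper, gs: int, ge: int) -> bool:
    for exon in tm.placement.exons:
        if exon.g_start <= gs and ge <= exon.g_end:
            return True
    return False


def _g_to_n_exonic(variant_g: SequenceVariant, tm: TranscriptMapper,
                   provider: DataProvider, record: TranscriptRecord,
                   ) -> SequenceVariant:
    pe = variant_g.posedit
    gs, ge = _nuc_interbase(pe)
    g_seq_ref = provider.get_seq(variant_g.ac, gs, ge)
    if pe.edit.kind == "ins":
        ref, alt = "", pe.edit.alt or ""
    else:
        ref, alt = edit_alleles(provider.get_seq(variant_g.ac), gs, ge, pe.edit)

    GS, GE = gs, ge
    if gs == ge:
        widened = tm._widen_abs_for_ins(gs)
        if widened is not None:
            GS, GE = widened
    if GS == GE:
        tx_gap = tm._tx_span_at_I_point(GS)
        if tx_gap is not None:
            # insertion at a transcript-only gap point: the edit replaces
            # the gap's transcript bases
            ts, te = tx_gap
        else:
            i, t = tm._abs_point_to_tx(GS, "end")
            ts = te = t
    else:
        # endpoints inside D widen via _abs_point_to_tx's D rule; the
        # transcript-start side is the absolute-low end only on plus strand
        if tm.strand == +1:
            _, t1 = tm._abs_point_to_tx(GS, "start")
            _, t2 = tm._abs_point_to_tx(GE, "end")
        else:
            _, t1 = tm._abs_point_to_tx(GE, "start")
            _, t2 = tm._abs_point_to_tx(GS, "end")
        ts, te = min(t1, t2), max(t1, t2)
        # re-derive the widened genomic interval from the transcript side so
        # both sequences agree on what the variant covers
        GS, GE, ts, te = _sync_g_interval(tm, ts, te, GS, GE)

    tx_seq = provider.get_seq(record.tx_ac)
    left = _splice_g_flank(tm, provider, variant_g.ac, tx_seq, GS, gs)
    right = _splice_g_flank(tm, provider, variant_g.ac, tx_seq, ge, GE)
    alt_w = left + alt + right
    if tm.strand == -1:
        alt_w = reverse_complement(alt_w)
    n_ref = tx_seq[ts:te]
    if not n_ref and not alt_w:
        # the edit touched only genome-only bases; the transcript is unchanged
        base = min(max(ts, 0), tm.tx_len - 1)
        posedit = _build_posedit(base, base + 1,
                                 tx_seq[base:base + 1], tx_seq[base:base + 1])
        return SequenceVariant(record.tx_ac, "n", posedit)
    posedit = _build_posedit(ts, te, n_ref, alt_w)
    return SequenceVariant(record.tx_ac, "n", posedit)


def _splice_g_flank(tm: TranscriptMapper, provider: DataProvider, g_ac: str,
                    tx_seq: str, lo: int, hi: int) -> str:
    """Flank content of a widened genomic interval as it reads on the
    transcript side (absolute genome orientation): genome-only (D) bases are
    dropped and mismatch (X) positions take the transcript's base, since the
    transcript is authoritative for its own sequence."""
    if lo >= hi:
        return ""
    out = []
    for p in range(lo, hi):  # abs interbase base [p, p+1)
        op, t = _locate_abs_base(tm, p)
        if op == "D":
            continue
        if op == "X":
            b = tx_seq[t]
            out.append(reverse_complement(b) if tm.strand == -1 else b)
        else:
            out.append(provider.get_seq(g_ac, p, p + 1))
    return "".join(out)


def _locate_abs_base(tm: TranscriptMapper, p: int) -> tuple[str, int]:
    """(segment op, transcript index) of the exonic base at abs interbase p."""
    for i, exon in enumerate(tm.placement.exons):
        if not (exon.g_start <= p < exon.g_end):
            continue
        a = (p - exon.g_start) if tm.strand == +1 else (exon.g_end - p - 1)
        for seg in tm._exon_segs[i]:
            if seg.op in ("M", "X", "D") and seg.a_lo <= a < seg.a_hi:
                return seg.op, seg.tx_lo + (a - seg.a_lo)
    raise NotOnTranscriptError(f"genomic base at {p} is not exonic")


def _sync_g_interval(tm: TranscriptMapper, ts: int, te: int,
                     GS: int, GE: int) -> tuple[int, int, int, int]:
    """Reconcile widened intervals across both sequences: widening on one
    side (into I or D bases) may require further widening on the other."""
    while True:
        ts2, te2 = tm._widen_tx(ts, te)
        gs2, ge2, ts3, te3 = tm.n_interval_to_g(ts2, te2)
        gs2, ge2 = min(gs2, GS), max(ge2, GE)
        if (gs2, ge2, ts3, te3) == (GS, GE, ts, te):
            return GS, GE, ts, te
        GS, GE, ts, te = gs2, ge2, ts3, te3


def _g_to_n_by_base(variant_g: SequenceVariant, tm: TranscriptMapper,
                    record: TranscriptRecord) -> SequenceVariant:
    pe = variant_g.posedit
    iv = pe.interval
    pos1 = tm._tx_base_of_g_base(iv.start.base)
    pos2 = tm._tx_base_of_g_base(iv.end.base)
    if (pos2._key() < pos1._key()):
        pos1, pos2 = pos2, pos1
    edit = pe.edit
    ref = edit.ref
    alt = edit.alt
    same_intron = pos1.offset and pos2.offset and (
        pos1.base == pos2.base
        or (pos1.offset > 0 > pos2.offset and pos2.base == pos1.base + 1)
    )
    if not same_intron:
        # the interval straddles an exon edge: the genomic reference
        # includes bases outside the transcript numbering
        ref = None
    if tm.strand == -1:
        if isinstance(ref, str) and ref:
            ref = reverse_complement(ref)
        if alt:
            alt = reverse_complement(alt)
    new_edit = Edit(edit.kind, ref=ref, alt=alt,
                    repeat_unit=edit.repeat_unit, repeat_count=edit.repeat_count)
    interval = BaseOffsetInterval(pos1, pos2)
    return SequenceVariant(record.tx_ac, "n", PosEdit(interval, new_edit))


# ---------------------------------------------------------------------------
# n. <-> c. arithmetic


def _n_pos_to_c(pos: BaseOffsetPosition, cds_start: int, cds_end: int,
                ) -> BaseOffsetPosition:
    t0 = pos.base - 1
    if t0 < cds_start:
        return BaseOffsetPosition(t0 - cds_start, pos.offset, Anchor.CDS_START)
    if t0 < cds_end:
        return BaseOffsetPosition(t0 - cds_start + 1, pos.offset, Anchor.CDS_START)
    return BaseOffsetPosition(t0 - cds_end + 1, pos.offset, Anchor.CDS_END)


def _c_pos_to_n(pos: BaseOffsetPosition, cds_start: int, cds_end: int,
                ) -> BaseOffsetPosition:
    if pos.anchor is Anchor.CDS_END:
        t = cds_end + pos.base
    elif pos.base > 0:
        t = cds_start + pos.base
    else:
        t = cds_start + pos.base + 1
    if t < 1:
        raise BoundsError(f"CDS position maps 5' of the transcript (n.{t})")
    return BaseOffsetPosition(t, pos.offset, Anchor.CDS_START)


def _convert_interval(variant: SequenceVariant, fn, cds_start: int,
                      cds_end: int, new_type: str) -> SequenceVariant:
    iv = variant.posedit.interval
    new_iv = BaseOffsetInterval(
        fn(iv.start, cds_start, cds_end), fn(iv.end, cds_start, cds_end)
    )
    pe = PosEdit(new_iv, variant.posedit.edit, variant.posedit.uncertain)
    return SequenceVariant(variant.ac, new_type, pe)


def n_to_c(variant_n: SequenceVariant, record: TranscriptRecord) -> SequenceVariant:
    """Renumber an n. variant relative to the CDS (lossless inverse of c_to_n)."""
    if variant_n.type != "n":
        raise HgvsError(f"expected an n. variant, got {variant_n.type}.")
    if not record.has_cds:
        raise NoCdsError(f"{record.tx_ac} has no CDS; cannot express c. coordinates")
    return _convert_interval(variant_n, _n_pos_to_c,
                             record.cds_start, record.cds_end, "c")


def c_to_n(variant_c: SequenceVariant, record: TranscriptRecord) -> SequenceVariant:
    """Renumber a c. variant in plain transcript coordinates."""
    if variant_c.type != "c":
        raise HgvsError(f"expected a c. variant, got {variant_c.type}.")
    if not record.has_cds:
        raise NoCdsError(f"{record.tx_ac} has no CDS; cannot express c. coordinates")
    return _convert_interval(variant_c, _c_pos_to_n,
                             record.cds_start, record.cds_end, "n")
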