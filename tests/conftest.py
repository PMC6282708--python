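"""Shared fixtures and the independent splice-and-compare oracle.

The oracle reconstructs "the transcript implied by an edited genome" by
walking the raw per-exon alignment records at single-base granularity — it
shares no code with the mapper, so agreement between the two is a real
cross-check, not a tautology.
"""

from __future__ import annotations

import numpy as np
import pytest

import hgvskit as hk
from hgvskit.edits import Edit
from hgvskit.position import BaseOffsetInterval, BaseOffsetPosition
from hgvskit.sequences import reverse_complement
from hgvskit.variant import PosEdit, SequenceVariant


@pytest.fixture(scope="session")
def bundle():
    """One deterministic synthetic bundle shared by the suite."""
    provider, truth = hk.generate_fixture(20240711)
    return provider, truth


@pytest.fixture()
def toy_provider():
    return hk.MemoryProvider({"toyA": "GCTTTA", "toyB": "GCTA"})


# --------------------------------------------------------------------------
# variant construction helpers


def nuc_variant(ac: str, type_: str, start: int, end: int | None,
                edit: Edit) -> SequenceVariant:
    iv = BaseOffsetInterval(
        BaseOffsetPosition(start),
        BaseOffsetPosition(end) if end is not None else None,
    )
    return SequenceVariant(ac, type_, PosEdit(iv, edit))


def random_tx_variant(rng: np.random.Generator, ac: str, tx: str,
                      lo: int = 1, hi: int | None = None) -> SequenceVariant:
    """A random sub/del/ins/delins/dup/identity at a random placement."""
    hi = hi if hi is not None else len(tx)
    kind = str(rng.choice(["sub", "del", "ins", "delins", "dup", "identity"]))
    b = int(rng.integers(lo, hi + 1))
    if kind == "sub":
        ref = tx[b - 1]
        alt = str(rng.choice([x for x in "ACGT" if x != ref]))
        return nuc_variant(ac, "n", b, None, Edit("sub", ref=ref, alt=alt))
    if kind == "ins":
        b = min(b, hi - 1)
        alt = "".join(rng.choice(list("ACGT"),
                                 size=int(rng.integers(1, 5))))
        return nuc_variant(ac, "n", b, b + 1, Edit("ins", alt=alt))
    length = int(rng.integers(1, 5))
    e = min(b + length - 1, hi)
    if kind == "del":
        return nuc_variant(ac, "n", b, e, Edit("del", ref=tx[b - 1:e]))
    if kind == "dup":
        return nuc_variant(ac, "n", b, e, Edit("dup", ref=tx[b - 1:e]))
    if kind == "identity":
        return nuc_variant(ac, "n", b, e, Edit("identity", ref=tx[b - 1:e]))
    alt = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 5))))
    return nuc_variant(ac, "n", b, e, Edit("delins", ref=tx[b - 1:e], alt=alt))


def variant_alleles(provider, variant) -> tuple[int, int, str]:
    """(interbase start, end, alt) of a nucleotide variant on its own
    sequence, materialized independently of the mapper."""
    pe = variant.posedit
    if pe.edit.kind == "ins":
        p = pe.interval.start.base
        return p, p, pe.edit.alt
    s, e = pe.interval.start.base - 1, pe.interval.end.base
    seq = provider.get_seq(variant.ac)
    from hgvskit.edits import edit_alleles

    _, alt = edit_alleles(seq, s, e, pe.edit)
    if pe.edit.kind == "dup":
        # edit_alleles returns ref+ref over the interval; as a replacement
        # of [s,e) that is exactly the duplicated content
        pass
    return s, e, alt


AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_hgvs_variant(rng: np.random.Generator) -> SequenceVariant:
    """A random well-formed SequenceVariant spanning every grammar
    production, for parse/format round-trip checks."""
    from hgvskit.position import AAPosition, Anchor, ProteinInterval

    type_ = str(rng.choice(["g", "m", "n", "c", "c", "p"]))
    ac = f"{'NP' if type_ == 'p' else str(rng.choice(['NC', 'NM']))}_" \
         f"{int(rng.integers(1, 999999)):06d}.{int(rng.integers(1, 9))}"
    if type_ in ("g", "m"):
        ac = f"NC_{int(rng.integers(1, 999999)):06d}.{int(rng.integers(1, 9))}"
    elif type_ in ("c", "n"):
        ac = f"{'NM' if type_ == 'c' else str(rng.choice(['NM', 'NR']))}_" \
             f"{int(rng.integers(1, 999999)):06d}.{int(rng.integers(1, 9))}"

    def seq(lo=1, hi=6):
        return "".join(rng.choice(list("ACGT"),
                                  size=int(rng.integers(lo, hi))))

    if type_ == "p":
        pos = int(rng.integers(1, 2000))
        aa = str(rng.choice(list(AA20)))
        kind = str(rng.choice(["sub", "identity", "del", "dup", "ins",
                               "delins", "fs"]))
        uncertain = bool(rng.integers(0, 2))
        if kind == "sub":
            alt = str(rng.choice(list(AA20 + "*")))
            pe = PosEdit(ProteinInterval(AAPosition(pos, aa)),
                         Edit("sub", ref=aa, alt=alt), uncertain)
        elif kind == "identity":
            pe = PosEdit(ProteinInterval(AAPosition(pos, aa)),
                         Edit("identity", ref=aa, alt=aa), uncertain)
        elif kind == "fs":
            alt = str(rng.choice(list(AA20)))
            term = int(rng.integers(1, 60))
            pe = PosEdit(ProteinInterval(AAPosition(pos, aa)),
                         Edit("fs", ref=aa, alt=alt, fs_term=term), uncertain)
        else:
            end = pos + int(rng.integers(1, 4))
            iv = ProteinInterval(AAPosition(pos, aa),
                                 AAPosition(end, str(rng.choice(list(AA20)))))
            if kind == "ins":
                iv = ProteinInterval(AAPosition(pos, aa),
                                     AAPosition(pos + 1,
                                                str(rng.choice(list(AA20)))))
                pe = PosEdit(iv, Edit("ins", alt="".join(
                    rng.choice(list(AA20), size=int(rng.integers(1, 4))))),
                    uncertain)
            elif kind == "delins":
                pe = PosEdit(iv, Edit("delins", alt="".join(
                    rng.choice(list(AA20), size=int(rng.integers(1, 4))))),
                    uncertain)
            else:
                pe = PosEdit(iv, Edit(kind), uncertain)
        return SequenceVariant(ac, "p", pe)

    def position(base_hint: int) -> BaseOffsetPosition:
        if type_ in ("g", "m"):
            return BaseOffsetPosition(base_hint)
        offset = 0
        anchor = Anchor.CDS_START
        base = base_hint
        if type_ == "c":
            which = rng.integers(0, 4)
            if which == 0:
                base = -int(base_hint)
            elif which == 1:
                anchor = Anchor.CDS_END
            if rng.integers(0, 2):
                offset = int(rng.integers(-200, 201)) or 5
        elif rng.integers(0, 3) == 0:
            offset = int(rng.integers(-200, 201)) or 5
        return BaseOffsetPosition(base, offset, anchor)

    b = int(rng.integers(1, 500000))
    kind = str(rng.choice(["sub", "del", "ins", "delins", "dup", "inv",
                           "identity", "repeat", "con"]))
    if kind == "sub":
        iv = BaseOffsetInterval(position(b))
        edit = Edit("sub", ref=seq(1, 2), alt=seq(1, 2))
    elif kind == "ins":
        start = position(b)
        end = BaseOffsetPosition(start.base, start.offset + 1, start.anchor) \
            if start.offset else BaseOffsetPosition(
                start.base + 1 if start.base != -1 else 1,
                0, start.anchor)
        iv = BaseOffsetInterval(start, end)
        edit = Edit("ins", alt=seq(1, 8))
    elif kind == "repeat":
        iv = BaseOffsetInterval(position(b))
        edit = Edit("repeat", repeat_unit=seq(1, 4),
                    repeat_count=int(rng.integers(2, 40)))
    elif kind == "con":
        iv = BaseOffsetInterval(BaseOffsetPosition(b),
                                BaseOffsetPosition(b + 50))
        src = BaseOffsetInterval(BaseOffsetPosition(b + 1000),
                                 BaseOffsetPosition(b + 1050))
        edit = Edit("con", con_source=(None, None, src))
        return SequenceVariant(ac, type_, PosEdit(iv, edit))
    else:
        span = int(rng.integers(1, 6))
        start = position(b)
        if start.offset:
            end = BaseOffsetPosition(start.base,
                                     start.offset + span - 1, start.anchor)
        else:
            e_base = start.base + span - 1
            if start.base < 0 <= e_base:
                e_base += 1
            end = BaseOffsetPosition(e_base if e_base != 0 else 1, 0,
                                     start.anchor)
        iv = BaseOffsetInterval(start, end)
        payload = rng.integers(0, 3)
        ref = seq(span, span + 1) if payload == 0 else (
            span if payload == 1 else None)
        if kind == "del":
            edit = Edit("del", ref=ref)
        elif kind == "dup":
            edit = Edit("dup", ref=ref)
        elif kind == "inv":
            edit = Edit("inv", ref=ref)
        elif kind == "identity":
            edit = Edit("identity")
        else:
            edit = Edit("delins", ref=ref, alt=seq(1, 8))
    return SequenceVariant(ac, type_, PosEdit(iv, edit))


# --------------------------------------------------------------------------
# the splice oracle


def spliced_transcript(provider, record, placement, gs: int, ge: int,
                       alt_abs: str) -> str:
    """Transcript implied by replacing genome[gs:ge) with ``alt_abs``.

    Walks the alignment records directly.  Conventions (shared with the
    package's documented gap policy): the edited region reads verbatim;
    outside it, mismatch (X) and transcript-only (I) columns take the
    transcript's own bases and genome-only (D) columns are skipped; I bases
    whose gap point falls inside (or at) the edited region are superseded
    by the region's content.
    """
    g = provider.get_seq(placement.g_ac)
    tx = provider.get_seq(record.tx_ac)
    if placement.strand == -1:
        # reflect everything into a plus-strand view
        n = len(g)
        g = reverse_complement(g)
        alt_abs = reverse_complement(alt_abs)
        gs, ge = n - ge, n - gs
        exons = [
            type(e)(e.tx_start, e.tx_end, n - e.g_end, n - e.g_start,
                    e.segments)
            for e in placement.exons
        ]
    else:
        exons = list(placement.exons)

    out: list[str] = []
    emitted = False

    def maybe_emit(cursor: int) -> None:
        nonlocal emitted
        if not emitted and cursor >= gs:
            out.append(alt_abs)
            emitted = True

    for exon in exons:
        t, a = exon.tx_start, 0
        for seg in exon.segments:
            g_lo = exon.g_start + a
            g_hi = g_lo + (seg.length if seg.op in ("M", "X", "D") else 0)
            if seg.op == "I":
                # transcript-only bases are superseded when the edited
                # region strictly covers their gap point, or when a pure
                # insertion lands exactly on it (replacement convention);
                # kept gap bases precede region content that starts here
                superseded = (gs < g_lo < ge) or (gs == ge == g_lo)
                if not superseded:
                    out.append(tx[t:t + seg.length])
                maybe_emit(g_lo)
                t += seg.length
            else:
                for p in range(g_lo, g_hi):
                    maybe_emit(p)
                    inside = gs <= p < ge
                    if seg.op == "M":
                        if not inside:
                            out.append(g[p])
                    elif seg.op == "X":
                        if not inside:
                            out.append(tx[t])
                    # D columns never reach the transcript
                    if seg.op in ("M", "X"):
                        t += 1
                a += seg.length
    if not emitted:
        out.append(alt_abs)
    return "".join(out)
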