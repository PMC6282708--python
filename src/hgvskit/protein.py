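"""Protein consequence prediction for CDS (c.) variants.

The transcript's CDS is edited, both the original and altered coding
sequences are translated, and the difference between the two proteins is
expressed in HGVS p. notation: synonymous (``p.(Gly2=)``), substitution,
in-frame deletion / insertion / duplication / delins, stop-gain,
frameshift with the distance to the first new stop (``fsTer#``), stop-loss
extension (``ext``), or ``p.?`` when no prediction is possible (intronic or
UTR-only variants, and variants disrupting the initiator codon).  All
predictions are flagged uncertain and print in parentheses.
"""

from __future__ import annotations

from .edits import Edit, edit_alleles
from .exceptions import NoCdsError
from .mapper import c_to_n
from .position import AAPosition, Anchor, ProteinInterval
from .provider import DataProvider
from .sequences import translate
from .variant import PosEdit, SequenceVariant


def _unknown(protein_ac: str) -> SequenceVariant:
    pe = PosEdit(ProteinInterval(AAPosition(1, "X")), Edit("unknown"),
                 uncertain=False)
    return SequenceVariant(protein_ac, "p", pe)


def c_to_p(variant_c: SequenceVariant, provider: DataProvider) -> SequenceVariant:
    """Predict the protein-level consequence of a c. variant."""
    record = provider.get_transcript(variant_c.ac)
    if not record.has_cds or not record.protein_ac:
        raise NoCdsError(f"{variant_c.ac} is non-coding; no protein consequence")
    protein_ac = record.protein_ac

    iv = variant_c.posedit.interval
    if iv.start.offset or iv.end.offset:
        return _unknown(protein_ac)  # intronic: splicing effects not predicted
    if iv.start.anchor is Anchor.CDS_END and iv.end.anchor is Anchor.CDS_END:
        return _unknown(protein_ac)  # entirely 3' UTR
    if iv.start.base < 0 and iv.end.base < 0:
        return _unknown(protein_ac)  # entirely 5' UTR

    var_n = c_to_n(variant_c, record)
    pe = var_n.posedit
    if pe.edit.kind == "ins":
        s = e = pe.interval.start.base
    else:
        s, e = pe.interval.start.base - 1, pe.interval.end.base

    tx = provider.get_seq(variant_c.ac)
    cs, ce = record.cds_start, record.cds_end
    if s < cs or e > ce:
        return _unknown(protein_ac)  # partially outside the CDS

    ref, alt = edit_alleles(tx, s, e, pe.edit)
    tail = tx[cs:]  # CDS plus 3' UTR, for frameshift stop scanning
    edited_tail = tail[: s - cs] + alt + tail[e - cs:]

    orig_aa = _until_stop(translate(tx[cs:ce]))
    new_aa = _until_stop(translate(edited_tail))
    frame_preserving = (len(alt) - len(ref)) % 3 == 0

    posedit = _diff_proteins(orig_aa, new_aa, frame_preserving,
                             first_codon=(s - cs) // 3)
    if posedit is None:
        return _unknown(protein_ac)
    return SequenceVariant(protein_ac, "p", posedit)


def _until_stop(aa: str) -> str:
    stop = aa.find("*")
    return aa if stop < 0 else aa[: stop + 1]


def _diff_proteins(orig: str, new: str, frame_preserving: bool,
                   first_codon: int) -> PosEdit | None:
    """Express new-vs-original protein as an HGVS p. posedit (uncertain)."""
    if new == orig:
        k = min(first_codon, len(orig) - 1)
        pos = AAPosition(k + 1, orig[k])
        return PosEdit(ProteinInterval(pos),
                       Edit("identity", ref=orig[k], alt=orig[k]),
                       uncertain=True)

    i = 0
    while i < min(len(orig), len(new)) and orig[i] == new[i]:
        i += 1

    if i == 0:
        return None  # initiator codon disrupted: no confident prediction
    if i >= len(new):
        return None  # protein truncated to nothing interpretable

    if i < len(orig) and orig[i] == "*":
        # stop-loss: translation extends past the original terminator
        new_stop = new.find("*", i)
        ext = (new_stop - i) if new_stop >= 0 else -1
        pos = AAPosition(i + 1, "*")
        return PosEdit(ProteinInterval(pos),
                       Edit("ext", ref="*", alt=new[i], fs_term=ext),
                       uncertain=True)

    if new[i] == "*":
        pos = AAPosition(i + 1, orig[i])
        return PosEdit(ProteinInterval(pos), Edit("sub", ref=orig[i], alt="*"),
                       uncertain=True)

    if not frame_preserving:
        new_stop = new.find("*", i)
        fs_term = (new_stop - i + 1) if new_stop >= 0 else -1
        pos = AAPosition(i + 1, orig[i])
        return PosEdit(ProteinInterval(pos),
                       Edit("fs", ref=orig[i], alt=new[i], fs_term=fs_term),
                       uncertain=True)

    # in-frame: strip the common suffix
    t = 0
    while (t < min(len(orig), len(new)) - i
           and orig[len(orig) - 1 - t] == new[len(new) - 1 - t]):
        t += 1
    i2, j2 = len(orig) - t, len(new) - t
    orig_seg, new_seg = orig[i:i2], new[i:j2]

    if len(orig_seg) == 1 and len(new_seg) == 1:
        pos = AAPosition(i + 1, orig_seg)
        return PosEdit(ProteinInterval(pos),
                       Edit("sub", ref=orig_seg, alt=new_seg), uncertain=True)
    if not new_seg:
        interval = ProteinInterval(AAPosition(i + 1, orig[i]),
                                   AAPosition(i2, orig[i2 - 1]))
        return PosEdit(interval, Edit("del"), uncertain=True)
    if not orig_seg:
        n = len(new_seg)
        if i >= n and orig[i - n:i] == new_seg:
            interval = ProteinInterval(AAPosition(i - n + 1, orig[i - n]),
                                       AAPosition(i, orig[i - 1]))
            return PosEdit(interval, Edit("dup"), uncertain=True)
        interval = ProteinInterval(AAPosition(i, orig[i - 1]),
                                   AAPosition(i + 1, orig[i]))
        return PosEdit(interval, Edit("ins", alt=new_seg), uncertain=True)
    interval = ProteinInterval(AAPosition(i + 1, orig[i]),
                               AAPosition(i2, orig[i2 - 1]))
    return PosEdit(interval, Edit("delins", alt=new_seg), uncertain=True)
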