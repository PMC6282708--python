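"""Normalization: trimming, 3' shifting, priority rewriting, boundaries."""

import logging

import numpy as np
import pytest

import hgvskit as hk
from hgvskit.edits import Edit, apply_edit
from hgvskit.normalizer import rewrite_edit, shift_3prime, trim_alleles
from hgvskit.provider import AlignmentSegment, Exon, Placement, TranscriptRecord

from conftest import nuc_variant, random_tx_variant


class TestElementarySteps:
    def test_trim_delins_to_deletion(self):
        assert trim_alleles("TTT", "TT", (3, 5)) == ("T", "", (5, 5))
        assert trim_alleles("TT", "T", (3, 4)) == ("T", "", (4, 4))

    def test_trim_to_identity(self):
        assert trim_alleles("A", "A", (7, 7)) == ("", "", (7, 7))

    def test_trim_to_insertion_flanks(self):
        ref, alt, iv = trim_alleles("T", "TA", (5, 5))
        assert (ref, alt) == ("", "A")
        assert iv == (5, 6)

    def test_shift_deletion_to_3prime(self):
        seq = "GCTTTA"
        fetch = lambda a, b: seq[a:b]
        assert shift_3prime("T", "", (3, 3), fetch, 0, 6) == ("T", "", (5, 5))

    def test_shift_respects_limit(self):
        seq = "GCTTTA"
        fetch = lambda a, b: seq[a:b]
        # a 3' limit at interbase 4 stops the shift one base early
        assert shift_3prime("T", "", (3, 3), fetch, 0, 4) == ("T", "", (4, 4))

    def test_shift_5prime_direction(self):
        seq = "GCTTTA"
        fetch = lambda a, b: seq[a:b]
        assert shift_3prime("T", "", (5, 5), fetch, 0, 6,
                            direction="5p") == ("T", "", (3, 3))

    def test_shift_uses_dynamic_window(self):
        seq = "A" + "T" * 500 + "G"
        calls = []

        def fetch(a, b):
            calls.append((a, b))
            return seq[a:b]

        ref, alt, iv = shift_3prime("T", "", (2, 2), fetch, 0, len(seq),
                                    window_size=20)
        assert iv == (501, 501)
        assert len(calls) > 1  # window was extended, not fetched whole
        assert max(b - a for a, b in calls) < len(seq)

    def test_rewrite_priorities(self):
        assert rewrite_edit("A", "G", (4, 4), "")[0].kind == "sub"
        assert rewrite_edit("T", "", (5, 5), "GCTT")[0].kind == "del"
        assert rewrite_edit("CA", "TG", (2, 3), "")[0].kind == "inv"
        edit, iv = rewrite_edit("", "A", (4, 5), "GCTA")
        assert (edit.kind, iv) == ("dup", (4, 4))
        assert rewrite_edit("", "G", (4, 5), "GCTA")[0].kind == "ins"
        assert rewrite_edit("AC", "TGG", (2, 3), "")[0].kind == "delins"


class TestNormalizePipeline:
    def test_equivalence_class_converges(self, toy_provider):
        spellings = [
            "toyA:g.3delT", "toyA:g.4delT", "toyA:g.5delT",
            "toyA:g.3_5delTTTinsTT", "toyA:g.3_4delTTinsT",
        ]
        normalized = {
            str(hk.normalize(hk.parse(s), toy_provider)) for s in spellings
        }
        assert normalized == {"toyA:g.5del"}

    def test_insertion_rewritten_as_duplication(self, toy_provider):
        v = hk.normalize(hk.parse("toyB:g.4_5insA"), toy_provider)
        assert str(v) == "toyB:g.4dup"

    def test_local_context_duplication_right_shift(self):
        # ACCGT duplicated, trailing ACAAG: shifts right by the common
        # prefix AC, two bases
        provider = hk.MemoryProvider({"chrT": "TTTT" + "ACCGT" + "ACAAG" + "TT"})
        v = hk.normalize(hk.parse("chrT:g.5_9dup"), provider)
        assert str(v) == "chrT:g.7_11dup"

    def test_identity_emitted_over_original_interval(self, toy_provider):
        v = hk.normalize(hk.parse("toyA:g.2_4delCTTinsCTT"), toy_provider)
        assert v.posedit.edit.kind == "identity"
        assert (v.posedit.interval.start.base,
                v.posedit.interval.end.base) == (2, 4)
        assert str(v) == "toyA:g.2_4="

    def test_unsupported_kinds_pass_through_with_notice(self, toy_provider,
                                                        caplog):
        v = hk.parse("toyA:g.2CT[4]")
        with caplog.at_level(logging.INFO, logger="hgvskit.normalizer"):
            out = hk.normalize(v, toy_provider)
        assert out == v
        assert any("not supported" in r.message for r in caplog.records)

    def test_invalid_variant_refuses_to_normalize(self, toy_provider):
        with pytest.raises(hk.HgvsValidationError):
            hk.normalize(hk.parse("toyA:g.3delA"), toy_provider)


def _single_exon_record(tx_ac, g_ac, tx_len, g_offset, cds=None):
    exon = Exon(0, tx_len, g_offset, g_offset + tx_len,
                (AlignmentSegment("M", tx_len),))
    return TranscriptRecord(tx_ac, "T", (Placement(g_ac, +1, (exon,)),),
                            cds_start=cds[0] if cds else None,
                            cds_end=cds[1] if cds else None)


class TestExonBoundaries:
    @pytest.fixture()
    def junction_provider(self):
        """Two exons; the deleted G at the 3' edge of exon 1 could shift
        into a run of Gs continuing across the intron."""
        exon1_tx = "ACGTACGTAC" * 5 + "TACAAAAAG"  # 59 bases, ends in G
        exon2_tx = "GGGGTACGTACGTACGTACT" + "A" * 20
        tx = exon1_tx + exon2_tx
        intron = "GGGGGGTTTTCCCCAAAATT" * 3
        genome = "TTTT" + exon1_tx + intron + exon2_tx + "TTTT"
        exons = (
            Exon(0, 59, 4, 63, (AlignmentSegment("M", 59),)),
            Exon(59, len(tx), 63 + len(intron), 63 + len(intron) + len(tx) - 59,
                 (AlignmentSegment("M", len(tx) - 59),)),
        )
        rec = TranscriptRecord("NM_J.1", "J", (Placement("NC_J.1", +1, exons),),
                               cds_start=0, cds_end=len(tx))
        return hk.MemoryProvider({"NM_J.1": tx, "NC_J.1": genome},
                                 {"NM_J.1": rec})

    def test_deletion_stops_at_exon_boundary(self, junction_provider):
        v = hk.normalize(hk.parse("NM_J.1:c.59delG"), junction_provider)
        assert v.posedit.interval.start.base == 59
        assert v.posedit.edit.kind == "del"

    def test_cross_boundaries_flag_allows_the_shift(self, junction_provider):
        cfg = hk.NormalizerConfig(cross_boundaries=True)
        v = hk.normalize(hk.parse("NM_J.1:c.59delG"), junction_provider, cfg)
        assert v.posedit.interval.start.base > 59

    def test_normalized_intervals_never_straddle_junctions(self, bundle):
        provider, truth = bundle
        rng = np.random.default_rng(5)
        norm = hk.Normalizer(provider, validate_first=False)
        checked = 0
        for t in truth.transcripts.values():
            junctions = [e for s, e in t.exon_tx_spans[:-1]]
            tx = provider.get_seq(t.tx_ac)
            for j in junctions:
                for _ in range(80):
                    b = max(1, j - int(rng.integers(0, 6)))
                    span = int(rng.integers(1, 4))
                    e = min(b + span - 1, j)  # seeded flush against junction
                    v = nuc_variant(t.tx_ac, "n", b, e,
                                    Edit("del", ref=tx[b - 1:e]))
                    out = norm.normalize(v)
                    iv = out.posedit.interval
                    if out.posedit.edit.kind == "ins":
                        s_i, e_i = iv.start.base, iv.start.base
                    else:
                        s_i, e_i = iv.start.base - 1, iv.end.base
                    assert not any(s_i < jj < e_i for jj in junctions)
                    checked += 1
        assert checked >= 1000


class TestNormalizeProperties:
    def test_idempotence_and_allele_preservation(self, bundle):
        provider, truth = bundle
        rng = np.random.default_rng(17)
        norm = hk.Normalizer(provider, validate_first=False)
        for _ in range(2000):
            t = list(truth.transcripts.values())[
                int(rng.integers(0, len(truth.transcripts)))]
            tx = provider.get_seq(t.tx_ac)
            v = random_tx_variant(rng, t.tx_ac, tx, lo=2, hi=len(tx) - 1)
            out = norm.normalize(v)
            assert norm.normalize(out) == out, f"not idempotent: {v}"
            before = apply_edit(tx, (v.posedit.interval.start.base,
                                     v.posedit.interval.end.base),
                                v.posedit.edit)
            iv = out.posedit.interval
            after = apply_edit(tx, (iv.start.base, iv.end.base),
                               out.posedit.edit)
            assert after == before, f"allele changed: {v} -> {out}"

    def test_intronic_variant_normalized_in_genomic_context(self, bundle):
        provider, truth = bundle
        t = next(t for t in truth.transcripts.values()
                 if len(t.exon_tx_spans) > 1)
        exon_end = t.exon_tx_spans[0][1]
        rec = provider.get_transcript(t.tx_ac)
        tm = hk.TranscriptMapper(rec, rec.placement_for())
        gb = tm._g_base_of_offset_pos(hk.BaseOffsetPosition(exon_end, +3))
        base = provider.get_seq(rec.placements[0].g_ac, gb - 1, gb)
        if rec.placements[0].strand == -1:
            from hgvskit.sequences import reverse_complement
            base = reverse_complement(base)
        v = hk.SequenceVariant(t.tx_ac, "n", hk.PosEdit(
            hk.BaseOffsetInterval(hk.BaseOffsetPosition(exon_end, +3)),
            Edit("sub", ref=base, alt="ACGT".replace(base, "")[0])))
        out = hk.normalize(v, provider)
        assert out.type == "n"  # projected out and back

    def test_intronic_without_context_returned_unchanged(self, caplog):
        provider = hk.MemoryProvider({"NM_1.1": "ACGT" * 100})
        v = hk.parse("NM_1.1:c.10+5del")
        with caplog.at_level(logging.INFO, logger="hgvskit.normalizer"):
            out = hk.normalize(v, provider)
        assert out == v
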