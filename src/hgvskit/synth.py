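"""Seeded synthetic fixture generation.

The generator emulates the reference data a transcript database and
sequence repository would serve: a random genome carrying multi-exon genes
on both strands, spliced transcripts with 5'/3' UTRs and clean open reading
frames, translated proteins, one non-coding transcript, one transcript with
a dual (pseudoautosomal-like) placement on a second chromosome, and —
optionally but by default — transcript-genome alignment discrepancies:

* ``tx_ins`` — bases present in the transcript but absent from the genome;
* ``genome_ins`` — bases present in the genome but absent from the
  transcript;
* ``mismatch`` — single-base substitution discrepancies (SNP-like sites
  where transcript and genome disagree).

Every injected discrepancy is recorded in a :class:`TruthTable` so tests
can aim variants directly at gap boundaries.  A fixed seed yields a
bit-identical bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import FixtureSpecError
from .provider import (
    AlignmentSegment,
    Exon,
    MemoryProvider,
    Placement,
    TranscriptRecord,
)
from .sequences import NUCLEOTIDES, reverse_complement, translate

#: codons that never appear inside generated ORFs
_STOP_CODONS = ("TAA", "TAG", "TGA")
_STOPLESS = [a + b + c
             for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES
             if a + b + c not in _STOP_CODONS]

DEFAULT_GAP_SPEC = {"tx_ins": 2, "genome_ins": 2, "len_range": (1, 4)}
DEFAULT_SNP_SPEC = {"mismatch": 3}


@dataclass
class GapEvent:
    """One injected alignment discrepancy, in transcript coordinates."""

    kind: str  # tx_ins | genome_ins | mismatch
    tx_ac: str
    exon_index: int
    tx_pos: int  # interbase transcript position where the event sits
    length: int
    tx_bases: str = ""  # transcript-side bases (tx_ins, mismatch)
    g_bases: str = ""  # genome-side bases (genome_ins, mismatch)


@dataclass
class TxTruth:
    tx_ac: str
    gene: str
    strand: int
    coding: bool
    cds: tuple[int, int] | None
    exon_tx_spans: list[tuple[int, int]]
    events: list[GapEvent] = field(default_factory=list)
    par: bool = False


@dataclass
class TruthTable:
    seed: int
    genome_acs: list[str]
    transcripts: dict[str, TxTruth] = field(default_factory=dict)

    def gapped(self) -> list[TxTruth]:
        return [t for t in self.transcripts.values()
                if any(e.kind != "mismatch" for e in t.events)]


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(NUCLEOTIDES), size=n))


def _rand_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + stop-free codons + one stop codon."""
    body = "".join(rng.choice(_STOPLESS, size=n_codons - 1))
    return "ATG" + body + str(rng.choice(_STOP_CODONS))


def _partition(rng: np.random.Generator, total: int, parts: int,
               minimum: int) -> list[int]:
    if parts * minimum > total:
        raise FixtureSpecError(
            f"cannot split {total} transcript bases into {parts} exons of "
            f">= {minimum} bases"
        )
    extra = total - parts * minimum
    cuts = np.sort(rng.integers(0, extra + 1, size=parts - 1))
    sizes = np.diff(np.concatenate([[0], cuts, [extra]]))
    return [minimum + int(s) for s in sizes]


def generate_fixture(
    seed: int,
    n_genes: int = 5,
    exon_count_range: tuple[int, int] = (2, 5),
    intron_len_range: tuple[int, int] = (60, 400),
    gap_spec: dict | None = None,
    snp_spec: dict | None = None,
    include_par: bool = True,
    include_noncoding: bool = True,
) -> tuple[MemoryProvider, TruthTable]:
    """Build a provider + truth table for ``n_genes`` synthetic genes.

    ``gap_spec`` gives total numbers of tx_ins/genome_ins events to inject
    across the bundle (``{"tx_ins": 2, "genome_ins": 2, "len_range": (1, 4)}``
    by default); ``snp_spec`` the number of substitution discrepancies.
    """
    if n_genes < 1:
        raise FixtureSpecError("need at least one gene")
    if intron_len_range[0] < 10:
        raise FixtureSpecError("introns must be at least 10 bases")
    gap_spec = DEFAULT_GAP_SPEC if gap_spec is None else gap_spec
    snp_spec = DEFAULT_SNP_SPEC if snp_spec is None else snp_spec
    rng = np.random.default_rng(seed)

    # distribute events over genes
    events: list[tuple[str, int]] = []
    len_range = gap_spec.get("len_range", (1, 4))
    for kind in ("tx_ins", "genome_ins"):
        for _ in range(gap_spec.get(kind, 0)):
            events.append((kind, int(rng.integers(len_range[0], len_range[1] + 1))))
    for _ in range(snp_spec.get("mismatch", 0)):
        events.append(("mismatch", 1))
    gene_of_event = rng.integers(0, n_genes, size=len(events))

    truth = TruthTable(seed=seed, genome_acs=["NC_F00001.9"])
    sequences: dict[str, str] = {}
    transcripts: dict[str, TranscriptRecord] = {}
    chrom_parts: list[str] = []
    chrom_pos = 0

    for g in range(n_genes):
        coding = not (include_noncoding and g == n_genes - 1 and n_genes > 1)
        par = include_par and g == 0
        tx_ac = (f"NM_F{g + 1:05d}.1" if coding else f"NR_F{g + 1:05d}.1")
        gene = f"SYNG{g + 1}"
        strand = +1 if g % 2 == 0 else -1
        my_events = [events[i] for i in range(len(events))
                     if gene_of_event[i] == g]

        tx_truth, tx_seq, g_region, exons_aln = _build_gene(
            rng, tx_ac, gene, strand, coding, exon_count_range,
            intron_len_range, my_events,
        )
        tx_truth.par = par

        # intergenic spacer, then the gene region (strand-reflected)
        spacer = _rand_seq(rng, int(rng.integers(200, 501)))
        chrom_parts.append(spacer)
        chrom_pos += len(spacer)
        region = g_region if strand == +1 else reverse_complement(g_region)
        region_len = len(g_region)
        exons_abs = _absolute_exons(exons_aln, chrom_pos, region_len, strand)
        chrom_parts.append(region)
        chrom_pos += region_len

        placements = [Placement("NC_F00001.9", strand, tuple(exons_abs), "X")]
        if par:
            # second placement on its own chromosome, same alignment
            pad5 = _rand_seq(rng, int(rng.integers(150, 300)))
            pad3 = _rand_seq(rng, int(rng.integers(150, 300)))
            sequences["NC_F00002.9"] = pad5 + region + pad3
            truth.genome_acs.append("NC_F00002.9")
            exons_y = _absolute_exons(exons_aln, len(pad5), region_len, strand)
            placements.append(
                Placement("NC_F00002.9", strand, tuple(exons_y), "Y")
            )

        protein_ac = None
        cds = tx_truth.cds
        if coding:
            protein_ac = f"NP_F{g + 1:05d}.1"
            sequences[protein_ac] = translate(tx_seq[cds[0]:cds[1]])[:-1]
        sequences[tx_ac] = tx_seq
        transcripts[tx_ac] = TranscriptRecord(
            tx_ac=tx_ac, gene=gene, placements=tuple(placements),
            cds_start=cds[0] if cds else None,
            cds_end=cds[1] if cds else None,
            protein_ac=protein_ac,
        )
        truth.transcripts[tx_ac] = tx_truth

    chrom_parts.append(_rand_seq(rng, int(rng.integers(200, 501))))
    sequences["NC_F00001.9"] = "".join(chrom_parts)
    return MemoryProvider(sequences, transcripts), truth


def _build_gene(rng, tx_ac, gene, strand, coding, exon_count_range,
                intron_len_range, my_events):
    """Construct one gene: transcript sequence first (clean ORF), then the
    genome region derived from it by inverting the injected discrepancies."""
    # transcript
    if coding:
        utr5 = _rand_seq(rng, int(rng.integers(20, 61)))
        orf = _rand_orf(rng, int(rng.integers(40, 120)))
        utr3 = _rand_seq(rng, int(rng.integers(30, 91)))
        tx_seq = utr5 + orf + utr3
        cds = (len(utr5), len(utr5) + len(orf))
    else:
        tx_seq = _rand_seq(rng, int(rng.integers(300, 700)))
        cds = None
    tx_len = len(tx_seq)

    n_exons = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
    exon_lens = _partition(rng, tx_len, n_exons, minimum=30)
    bounds = np.cumsum([0] + exon_lens)
    exon_tx_spans = [(int(bounds[i]), int(bounds[i + 1]))
                     for i in range(n_exons)]

    # place events at interbase transcript positions well inside exons,
    # non-overlapping
    placed: list[GapEvent] = []
    taken: list[tuple[int, int]] = []
    for kind, length in my_events:
        for _ in range(50):  # rejection sampling
            ei = int(rng.integers(0, n_exons))
            lo, hi = exon_tx_spans[ei]
            if hi - lo < length + 12:
                continue
            pos = int(rng.integers(lo + 5, hi - 5 - length + 1))
            span = (pos - 4, pos + length + 4)
            if any(not (span[1] <= a or b <= span[0]) for a, b in taken):
                continue
            taken.append(span)
            placed.append(GapEvent(kind, tx_ac, ei, pos, length))
            break
        else:
            raise FixtureSpecError(
                f"could not place a {kind} event of length {length} in {tx_ac}"
            )
    placed.sort(key=lambda e: e.tx_pos)

    # per-exon segments + genome-side exon sequence (alignment orientation)
    exons_aln: list[tuple[int, int, list[AlignmentSegment], str]] = []
    for ei, (lo, hi) in enumerate(exon_tx_spans):
        segs: list[AlignmentSegment] = []
        g_piece: list[str] = []
        cursor = lo
        for ev in [e for e in placed if e.exon_index == ei]:
            if ev.tx_pos > cursor:
                segs.append(AlignmentSegment("M", ev.tx_pos - cursor))
                g_piece.append(tx_seq[cursor:ev.tx_pos])
            if ev.kind == "tx_ins":
                segs.append(AlignmentSegment("I", ev.length))
                ev.tx_bases = tx_seq[ev.tx_pos:ev.tx_pos + ev.length]
                cursor = ev.tx_pos + ev.length
            elif ev.kind == "genome_ins":
                segs.append(AlignmentSegment("D", ev.length))
                ev.g_bases = _rand_seq(rng, ev.length)
                g_piece.append(ev.g_bases)
                cursor = ev.tx_pos
            else:  # mismatch
                tx_base = tx_seq[ev.tx_pos]
                others = [b for b in NUCLEOTIDES if b != tx_base]
                g_base = str(rng.choice(others))
                segs.append(AlignmentSegment("X", 1))
                ev.tx_bases, ev.g_bases = tx_base, g_base
                g_piece.append(g_base)
                cursor = ev.tx_pos + 1
        if hi > cursor:
            segs.append(AlignmentSegment("M", hi - cursor))
            g_piece.append(tx_seq[cursor:hi])
        exons_aln.append((lo, hi, segs, "".join(g_piece)))

    # genome region in alignment orientation: exon pieces joined by introns
    region_parts: list[str] = []
    exon_aln_spans: list[tuple[int, int]] = []
    a = 0
    for i, (lo, hi, segs, piece) in enumerate(exons_aln):
        if i > 0:
            intron = _rand_seq(
                rng, int(rng.integers(intron_len_range[0],
                                      intron_len_range[1] + 1)))
            region_parts.append(intron)
            a += len(intron)
        region_parts.append(piece)
        exon_aln_spans.append((a, a + len(piece)))
        a += len(piece)
    g_region = "".join(region_parts)

    exon_records = [
        (lo, hi, span, segs)
        for (lo, hi, segs, _), span in zip(exons_aln, exon_aln_spans)
    ]
    truth = TxTruth(tx_ac=tx_ac, gene=gene, strand=strand, coding=coding,
                    cds=cds, exon_tx_spans=exon_tx_spans, events=placed)
    return truth, tx_seq, g_region, exon_records


def _absolute_exons(exon_records, offset: int, region_len: int,
                    strand: int) -> list[Exon]:
    out = []
    for lo, hi, (a1, a2), segs in exon_records:
        if strand == +1:
            g1, g2 = offset + a1, offset + a2
        else:
            g1, g2 = offset + region_len - a2, offset + region_len - a1
        out.append(Exon(lo, hi, g1, g2, tuple(segs)))
    return out
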