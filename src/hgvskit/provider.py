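"""Read-only data provider: sequences, exon structures, CDS bounds, and
per-exon transcript-genome alignments.

The provider is the seam where, in a production deployment, a transcript
database and sequence repository would attach.  Here it is backed either by
in-memory dictionaries (:class:`MemoryProvider`) or by a fixture directory
holding a JSON manifest plus a FASTA file (:func:`load_fixture`), both of
which are validated for internal consistency at load time: alignment
segment sums must reconcile exon lengths on both the transcript and genome
side, exon transcript spans must tile the transcript, and CDS bounds must
lie within it.

All stored coordinates are interbase (0-based, half-open); 1-based numbers
exist only inside HGVS strings.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import (
    BoundsError,
    FixtureIntegrityError,
    SequenceUnavailableError,
    TranscriptUnavailableError,
)

#: alignment ops: M match, X mismatch, I transcript-only bases (absent from
#: the genome), D genome-only bases (absent from the transcript)
SEGMENT_OPS = ("M", "X", "I", "D")


@dataclass(frozen=True)
class AlignmentSegment:
    op: str
    length: int

    def __post_init__(self) -> None:
        if self.op not in SEGMENT_OPS:
            raise FixtureIntegrityError(f"unknown alignment op {self.op!r}")
        if self.length <= 0:
            raise FixtureIntegrityError("alignment segments have positive length")

    @property
    def tx_len(self) -> int:
        return self.length if self.op in ("M", "X", "I") else 0

    @property
    def g_len(self) -> int:
        return self.length if self.op in ("M", "X", "D") else 0


def parse_cigar(text: str) -> tuple[AlignmentSegment, ...]:
    segs = []
    for m in re.finditer(r"(\d+)([MXID])|(.)", text):
        if m.group(3) is not None:
            raise FixtureIntegrityError(f"malformed cigar {text!r}")
        segs.append(AlignmentSegment(m.group(2), int(m.group(1))))
    return tuple(segs)


def cigar_string(segs) -> str:
    return "".join(f"{s.length}{s.op}" for s in segs)


@dataclass(frozen=True)
class Exon:
    """One exon: transcript span, genomic span (absolute, start < end), and
    the gapped alignment between them, listed in transcript order."""

    tx_start: int
    tx_end: int
    g_start: int
    g_end: int
    segments: tuple[AlignmentSegment, ...]

    def check(self) -> None:
        tx_sum = sum(s.tx_len for s in self.segments)
        g_sum = sum(s.g_len for s in self.segments)
        if tx_sum != self.tx_end - self.tx_start:
            raise FixtureIntegrityError(
                f"segment transcript lengths sum to {tx_sum}, exon spans "
                f"{self.tx_end - self.tx_start}"
            )
        if g_sum != self.g_end - self.g_start:
            raise FixtureIntegrityError(
                f"segment genomic lengths sum to {g_sum}, exon spans "
                f"{self.g_end - self.g_start}"
            )


@dataclass(frozen=True)
class Placement:
    """One genomic placement of a transcript (PAR transcripts have two)."""

    g_ac: str
    strand: int  # +1 or -1
    exons: tuple[Exon, ...]  # transcript order
    name: str | None = None  # e.g. "X"/"Y" for pseudoautosomal placements

    def check(self, tx_len: int) -> None:
        if self.strand not in (+1, -1):
            raise FixtureIntegrityError("strand must be +1 or -1")
        pos = 0
        for exon in self.exons:
            exon.check()
            if exon.tx_start != pos:
                raise FixtureIntegrityError("exon transcript spans must be contiguous")
            pos = exon.tx_end
        if pos != tx_len:
            raise FixtureIntegrityError(
                f"exons cover {pos} transcript bases, sequence has {tx_len}"
            )
        g_spans = [(e.g_start, e.g_end) for e in self.exons]
        if self.strand == -1:
            g_spans = g_spans[::-1]
        for (s1, e1), (s2, e2) in zip(g_spans, g_spans[1:]):
            if e1 > s2:
                raise FixtureIntegrityError("genomic exon spans overlap or are unordered")

    @property
    def g_span(self) -> tuple[int, int]:
        return (min(e.g_start for e in self.exons), max(e.g_end for e in self.exons))


@dataclass(frozen=True)
class TranscriptRecord:
    tx_ac: str
    gene: str
    placements: tuple[Placement, ...]
    cds_start: int | None = None  # interbase on the transcript
    cds_end: int | None = None
    protein_ac: str | None = None

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None and self.cds_end is not None

    def placement_for(self, g_ac: str | None = None,
                      par_choice: str = "X") -> Placement:
        """Select a genomic placement: by genomic accession when given, else
        by pseudoautosomal choice (named placements), else the primary."""
        if g_ac is not None:
            for p in self.placements:
                if p.g_ac == g_ac:
                    return p
            raise TranscriptUnavailableError(
                f"{self.tx_ac} has no placement on {g_ac}"
            )
        if len(self.placements) > 1:
            for p in self.placements:
                if p.name == par_choice:
                    return p
        return self.placements[0]

    def check(self, tx_len: int) -> None:
        if not self.placements:
            raise FixtureIntegrityError(f"{self.tx_ac}: no genomic placement")
        for p in self.placements:
            p.check(tx_len)
        if self.has_cds:
            if not (0 <= self.cds_start < self.cds_end <= tx_len):
                raise FixtureIntegrityError(f"{self.tx_ac}: CDS outside transcript")


class DataProvider:
    """Interface expected by the validator, normalizer, and mapper."""

    def get_seq(self, ac: str, start: int | None = None,
                end: int | None = None) -> str:
        raise NotImplementedError

    def seq_length(self, ac: str) -> int:
        raise NotImplementedError

    def get_transcript(self, tx_ac: str) -> TranscriptRecord:
        raise NotImplementedError

    def get_transcripts_for_region(self, g_ac: str, start_i: int,
                                   end_i: int) -> list[TranscriptRecord]:
        raise NotImplementedError

    def transcripts(self) -> list[str]:
        raise NotImplementedError


class MemoryProvider(DataProvider):
    """Dictionary-backed provider; also the object a loaded fixture becomes."""

    def __init__(self, sequences: dict[str, str],
                 transcripts: dict[str, TranscriptRecord] | None = None,
                 validate: bool = True):
        self._sequences = dict(sequences)
        self._transcripts = dict(transcripts or {})
        if validate:
            self._check_integrity()

    def _check_integrity(self) -> None:
        for tx_ac, rec in self._transcripts.items():
            if tx_ac not in self._sequences:
                raise FixtureIntegrityError(f"no sequence stored for {tx_ac}")
            rec.check(len(self._sequences[tx_ac]))
            for p in rec.placements:
                if p.g_ac not in self._sequences:
                    raise FixtureIntegrityError(
                        f"{tx_ac}: placement genome {p.g_ac} has no sequence"
                    )
                lo, hi = p.g_span
                if hi > len(self._sequences[p.g_ac]):
                    raise FixtureIntegrityError(
                        f"{tx_ac}: exons exceed {p.g_ac} length"
                    )
            if rec.protein_ac and rec.protein_ac not in self._sequences:
                raise FixtureIntegrityError(
                    f"{tx_ac}: protein {rec.protein_ac} has no sequence"
                )

    # -- queries ----------------------------------------------------------
    def get_seq(self, ac: str, start: int | None = None,
                end: int | None = None) -> str:
        if ac not in self._sequences:
            raise SequenceUnavailableError(f"sequence data not available for {ac}")
        seq = self._sequences[ac]
        if start is None and end is None:
            return seq
        start = 0 if start is None else start
        end = len(seq) if end is None else end
        if not (0 <= start <= end <= len(seq)):
            raise BoundsError(
                f"slice [{start},{end}) outside 0..{len(seq)} of {ac}"
            )
        return seq[start:end]

    def seq_length(self, ac: str) -> int:
        if ac not in self._sequences:
            raise SequenceUnavailableError(f"sequence data not available for {ac}")
        return len(self._sequences[ac])

    def get_transcript(self, tx_ac: str) -> TranscriptRecord:
        if tx_ac not in self._transcripts:
            raise TranscriptUnavailableError(f"transcript data not available for {tx_ac}")
        return self._transcripts[tx_ac]

    def get_transcripts_for_region(self, g_ac: str, start_i: int,
                                   end_i: int) -> list[TranscriptRecord]:
        hits = []
        for tx_ac in sorted(self._transcripts):
            rec = self._transcripts[tx_ac]
            for p in rec.placements:
                lo, hi = p.g_span
                if p.g_ac == g_ac and start_i >= lo and end_i <= hi:
                    hits.append(rec)
                    break
        return hits

    def transcripts(self) -> list[str]:
        return sorted(self._transcripts)


# --------------------------------------------------------------------------
# fixture directory (JSON manifest + FASTA)


def _record_to_json(rec: TranscriptRecord) -> dict:
    return {
        "tx_ac": rec.tx_ac,
        "gene": rec.gene,
        "cds": [rec.cds_start, rec.cds_end] if rec.has_cds else None,
        "protein_ac": rec.protein_ac,
        "placements": [
            {
                "g_ac": p.g_ac,
                "strand": p.strand,
                "name": p.name,
                "exons": [
                    {
                        "tx": [e.tx_start, e.tx_end],
                        "g": [e.g_start, e.g_end],
                        "cigar": cigar_string(e.segments),
                    }
                    for e in p.exons
                ],
            }
            for p in rec.placements
        ],
    }


def _record_from_json(d: dict) -> TranscriptRecord:
    placements = []
    for p in d["placements"]:
        exons = tuple(
            Exon(e["tx"][0], e["tx"][1], e["g"][0], e["g"][1],
                 parse_cigar(e["cigar"]))
            for e in p["exons"]
        )
        placements.append(Placement(p["g_ac"], p["strand"], exons, p.get("name")))
    cds = d.get("cds")
    return TranscriptRecord(
        tx_ac=d["tx_ac"],
        gene=d["gene"],
        placements=tuple(placements),
        cds_start=cds[0] if cds else None,
        cds_end=cds[1] if cds else None,
        protein_ac=d.get("protein_ac"),
    )


def save_fixture(provider: MemoryProvider, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "transcripts": [
            _record_to_json(provider.get_transcript(ac))
            for ac in provider.transcripts()
        ]
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    records = [
        SeqRecord(Seq(provider.get_seq(ac)), id=ac, description="")
        for ac in sorted(provider._sequences)
    ]
    SeqIO.write(records, directory / "sequences.fa", "fasta")


def load_fixture(directory: str | Path) -> MemoryProvider:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    sequences = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(directory / "sequences.fa"), "fasta")
    }
    transcripts = {
        d["tx_ac"]: _record_from_json(d) for d in manifest["transcripts"]
    }
    return MemoryProvider(sequences, transcripts)
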