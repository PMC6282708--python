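# Methods

This note documents the models, conventions, and numerical choices behind
`hgvskit`, and what the synthetic-data-backed test suite does and does not
demonstrate about behaviour on real reference data.

## Coordinate model

All internal arithmetic uses interbase coordinates (0-based, half-open);
1-based inclusive HGVS numbering exists only at the parse/format boundary.
This makes insertion points and empty intervals unambiguous: an insertion
"between bases 4 and 5" is the single interbase point 4, not a
two-endpoint interval with special rules.

Positions carry the full HGVS dialect: a signed base (never 0; `c.-1`
abuts `c.1`), a signed intron offset (0 for exonic and genomic positions),
and an anchor — CDS start for ordinary and 5′-UTR positions, CDS end for
`*` (3′-UTR) positions. Positions are totally ordered by (anchor,
zero-collapsed base, offset), which is exactly HGVS transcription order;
interval well-formedness (`start ≤ end`, insertion flanks adjacent) is a
*validation* outcome, not a construction-time constraint, so malformed
records can be represented, reported on, and counted rather than crashing
a batch.

Mitochondrial (`m.`) coordinates behave identically to `g.` apart from the
printed letter.

## Grammar

The parser is a hand-written recursive-descent implementation with one rule
per variant kind, tried longest-match-first (`delins` before `del`+`ins`;
repeats `CAG[7]` before compound-allele brackets). Two rejection classes
are deliberately distinct exception types: *syntax errors* (e.g. `ins8` —
insertions must state a sequence, so declared-length insertions and
`delTins6` fail at parse) and *unsupported nomenclature* — uncertain
positions (`(?_17019)`), compound/mosaic/chimeric alleles, translocations,
ISCN — which may be legal HGVS that this package does not model.
Declared-length deletions (`del174`) parse into a declared-length
reference, because discordant-length records must be representable in
order to be reported as invalid. Sequence characters are upper-cased on
parse; accession case is preserved; whitespace is rejected rather than
stripped, since these strings function as database identifiers.

Formatting is configurable without touching the stored object:
`max_ref_length` (default 0) suppresses explicit del/dup/inv reference
sequences longer than the threshold (`None` = always print); `p_3_letter`
(default on) selects amino-acid token width; `p_term_asterisk` (default
off) prints stops as `*` in 3-letter mode. Declared lengths always print.

## Validation

Validation runs in two stages. Intrinsic criteria (no external data):
i1 start ≤ end; i2 insertion flanks adjacent; i3 accession prefix
compatible with coordinate type (`NM_` → `c.`/`n.`, `NC_` → `g.`/`m.`,
`NP_` → `p.`; unknown prefixes are unconstrained); i4 stated reference
length equals the interval span; i5 edit arity matches its kind. Extrinsic
criteria (provider-backed, run only when intrinsic found no ERROR, being
the more expensive stage): e1 coordinates within the sequence/alignment
bounds (an insertion's 3′ flank may be the position one past the sequence
end, so an insertion after the final base is representable); e2 stated
reference agrees with the sequence — duplication and inversion references
are checked against their interval; e3 intronic reference bases on a
transcript variant. e3 returns WARNING only when no genomic alignment is
available; with an alignment, the intronic base *is* checked against the
genome and becomes VALID or ERROR.

Each criterion reports (level, message) into an ordered report and cannot
abort the run; the overall level is the maximum. Default mode never
raises — errors are report outcomes — while strict mode raises whenever
the overall level is not VALID. A missing sequence altogether is a
data-availability error (exception), not a validation level: "we have no
data" and "the data contradicts you" are different facts.

## Normalization

Three composable steps, preceded by validation (ERROR aborts):

1. **Trim**: remove the common prefix, then the common suffix, of the
   materialized reference and alternate alleles, adjusting the interval.
   If both allele strings empty out, the variant is an identity and is
   emitted as `=` over the original interval. (Prefix-first vs suffix-first
   only changes the intermediate placement; the subsequent shift makes the
   result identical.)
2. **Shift**: a trimmed pure insertion or deletion is rotated toward 3′
   while the next reference base equals the allele head (O(shift), not
   O(window²)); anything with bases on both sides after trimming has no
   equivalent placements. Reference bases are fetched through a dynamic
   window starting at `window_size` (default 20) bases and doubling when
   the shift reaches its edge, so long homopolymer runs never require
   unbounded reads. The shift stops at the sequence end and, for `c.`/`n.`
   variants with `cross_boundaries` off (the default), at the containing
   exon's 3′ boundary — a transcript placement shifted across a junction
   would denote different genomic bases. A `5p` direction implements the
   mirrored (VCF-style) convention.
3. **Rewrite**: the shifted change is re-expressed as the highest-priority
   kind that exactly represents it: both alleles length 1 → substitution;
   alt empty → deletion; alleles reverse-complementary (length > 1) →
   inversion; inserted bases equal to the immediately preceding reference
   bases → duplication (interval moved onto the duplicated bases);
   otherwise insertion or deletion–insertion. Conversions are never
   emitted by the rewriter (no defined rewrite rule into or out of them);
   conversion and repeat edits pass through normalization unchanged with a
   logged notice.

`c.` variants are renumbered into plain transcript coordinates for the
computation and back afterwards. Intronic variants (offset ≠ 0) are
normalized in genomic context — projected to the genome, normalized there,
projected back — when an alignment exists; otherwise they are returned
unchanged with a notice.

## Transcript–genome projection

Per-exon alignments are stored as segment lists with four ops: `M` match,
`X` mismatch, `I` transcript-only bases, `D` genome-only bases (a CIGAR
with explicit mismatches). Introns are not alignment segments; intronic
positions are computed from exon edges as base-plus-offset, choosing the
closest edge and breaking exact ties toward the upstream exon (a `+`
offset). Minus-strand transcripts are handled in an "alignment space"
whose genomic offsets increase 5′→3′ along the transcript and are
reflected into absolute coordinates at the edges; alleles are
reverse-complemented once, at the end.

**Gap policy.** A variant interval intersecting a gap is widened to the
smallest interval whose endpoints are unambiguous on both sequences, and
the projected alternate allele is recomputed from the full edited source
sequence over the widened interval, so allele equivalence holds by
construction. The specific conventions:

* endpoints *inside* gap bases widen to the gap boundary; endpoints that
  merely *abut* a gap exclude it;
* an interval covering transcript-only (`I`) bases must cover their
  genomic gap point strictly, so the widened region is extended by one
  more transcript base when the gap would sit flush at the region edge;
* a pure insertion at a gap point *replaces* the gap's transcript bases
  (the alt carries them), making the two projection directions mutually
  consistent;
* mismatch (`X`) positions never trigger widening; in widened flanks the
  transcript's own base is authoritative;
* deleting *only* transcript-only bases has no genomic image — the genome
  never contained them — and projects to a genomic identity. This is the
  one case where transcript-level allele equivalence is unattainable by
  any genomic variant.

The splice-and-compare oracle in the test suite re-derives "the transcript
implied by an edited genome" by walking the raw alignment records at
single-base granularity, independent of the mapper, and confirms allele
equivalence on tens of thousands of generated variants, including all four
gap-interaction classes (within / exactly covering / partially covering /
spanning).

The high-level pipelines fix the operation order: **validate before
projection** (coordinates beyond the transcript raise; nothing is ever
extrapolated), **replace the reference after projection** (at SNP-like
alignment mismatches the projected variant carries the target sequence's
base), and **renormalize on the target** (a 3′-most placement on a
minus-strand transcript is generally not 3′-most on the plus-strand
genome). Pseudoautosomal transcripts hold two named placements; the X
placement is assumed unless the caller selects Y.

Round-trip identity (transcript → genome → transcript and the reverse)
holds exactly for variants whose normalized placements stay clear of
alignment gaps and exon junctions; a variant normalized *across* a gap
point on the genome, or spanning a junction, projects position-faithfully
but not string-identically (the same classes of exception that appear in
large-scale round-trip audits of public databases). The equivalence oracle,
not string identity, is the guarantee for those cases.

## Protein consequences

For an exonic `c.` variant on a coding transcript, the CDS is edited and
both coding sequences translated (standard code, via Biopython). The
difference is classified, in order: identical proteins → synonymous
(`p.(Xaa#=)` at the first codon the variant touches); first changed
residue is the original stop → extension (`ext`, with the distance to the
next in-frame stop in the 3′ UTR); new residue is a stop → nonsense;
frame-disrupting length change → frameshift, scanning the shifted frame
(CDS plus 3′ UTR) to the first new stop (`fsTer#` counts that stop's
position relative to the first changed residue, `Ter?` if none is found);
otherwise in-frame substitution / deletion / duplication / insertion /
delins by common-affix stripping. Initiator-codon disruption, UTR-only and
intronic variants yield `p.?` — no confident prediction — rather than an
exception. All predictions are flagged uncertain and print in parentheses.
Extension notation is heuristic (flagged experimental); rigorous
splice-effect and NMD prediction are out of scope.

## Data provider and fixtures

The provider interface (`get_seq`, `seq_length`, `get_transcript`,
`get_transcripts_for_region`) is the seam where a transcript database and
sequence repository would attach in production; here it is backed by
in-memory dictionaries or a fixture directory (JSON manifest +
uncompressed FASTA; the manifest schema is what `save_fixture` writes and
`_record_from_json` reads — transcript accession, gene, CDS interbase
bounds, protein accession, and per-placement exon records with `tx`/`g`
interbase spans and an `MXID` cigar). Every bundle is integrity-checked at
load: segment sums must reconcile exon lengths on both sides, exon
transcript spans must tile the transcript, genomic spans must be ordered
by strand and fit the chromosome, and CDS bounds must be internal.
Providers are pure: repeated queries return identical results. There is no
network code anywhere.

## Synthetic-data generator

`generate_fixture(seed, …)` emulates the reference data the package
consumes. Defaults, chosen to resemble compact vertebrate genes while
keeping the bundle desk-sized: 5 genes alternating strands; 2–5 exons of
≥ 30 bases; introns of 60–400 bases; coding transcripts with 20–60-base
5′ UTRs, clean ORFs of 40–120 codons (ATG start, stop-free body, single
terminator — so translation-based tests have unambiguous expected
values), and 30–90-base 3′ UTRs; one non-coding transcript; one transcript
dually placed on a second chromosome (pseudoautosomal analog, placements
named X and Y). Alignment discrepancies are injected by default — 2
transcript-only gaps, 2 genome-only gaps (1–4 bases), 3 single-base
mismatches per bundle, placed ≥ 5 bases inside exons and non-overlapping —
and every event's kind, exon, transcript position, and both-side bases are
recorded in a `TruthTable`, which is how tests aim variants precisely at
gap boundaries. The transcript is generated first and the genome derived
from it by inverting the events, so the alignment is correct by
construction; a fixed seed is bit-reproducible.

What the generator does *not* emulate — hence what passing tests do not
show: real RefSeq/assembly accessions and their versioned histories,
repeat-rich and low-complexity sequence (random uniform bases make long
homopolymer shifts rarer than in real genomes; dedicated tests construct
such contexts explicitly), overlapping gene models on opposite strands,
multi-transcript genes, alternative splicing, selenoproteins and other
non-standard translation, and alignment gaps at exon edges (events are
kept interior, as edge gaps are not well-formed in exon-anchored
alignments).

## Problem sizes

The test suite uses one shared bundle (seed 20240711) plus
purpose-built fixtures; the property tests run 10⁴ parse/format round
trips, 10⁴ normalization idempotence/allele-preservation checks, ≥ 10³
projection round trips, ≥ 10³ gap-class equivalence cases across ~40
seeded bundles, and 500 reference-corruption detections. The whole suite
completes in a few seconds on one CPU. `scripts/acceptance.py` runs the
toy worked examples only (sequences of 4–32 M bases, built in memory at
run time).
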