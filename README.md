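# hgvskit

Parse, validate, normalize, format, and project sequence variants described
in [HGVS nomenclature](https://varnomen.hgvs.org/) — e.g.
`NM_000059.3:c.201_202dupGA` — across genome (`g.`/`m.`), transcript
(`n.`/`c.`), and protein (`p.`) coordinate systems, with correct handling of
gapped transcript–genome alignments.

HGVS strings are the lingua franca of clinical genetics, but they are easy
to write inconsistently: the same allele has many spellings, reference
bases go stale, and transcript↔genome coordinate conversion silently breaks
for the hundreds of RefSeq transcripts whose genomic alignments contain
indels. `hgvskit` is aimed at people building variant-interpretation
pipelines who need a single, locally-runnable component that

* **parses and formats** every common variant kind (substitution, deletion,
  insertion, deletion–insertion, duplication, inversion, conversion,
  repeat, identity) through a strict grammar, with configurable output
  (reference-length suppression, 1-/3-letter amino acids, `Ter` vs `*`);
* **validates** in two stages — intrinsic self-consistency, then extrinsic
  checks against reference data — reporting each criterion as
  `VALID`/`WARNING`/`ERROR` so that unambiguously valid, plausibly valid,
  and unambiguously invalid variants are distinguishable (strict mode turns
  `WARNING` into failure);
* **normalizes** to the canonical HGVS form: trim the shared allele bases,
  shift as far 3′ as an equivalent placement exists (`GCTTTA` → `GCTTA` is
  `5del`, never `3delT`), and rewrite the edit at the highest nomenclature
  priority (substitution > deletion > inversion > duplication >
  insertion > deletion–insertion), without crossing exon–intron boundaries
  on transcripts;
* **projects** variants between genome, transcript, and protein, widening
  intervals that intersect alignment gaps so the projected allele remains
  equivalent, validating *before* projection (no extrapolated
  coordinates), replacing the reference from the target sequence *after*
  projection, and renormalizing on the target strand. Pseudoautosomal
  transcripts carry dual placements selected by an X/Y switch.

All reference data is served through a local, read-only data-provider
interface backed by a JSON-manifest + FASTA fixture directory; a seeded
generator (`hgvskit.generate_fixture`) synthesizes realistic bundles —
multi-exon genes on both strands, UTRs and clean ORFs, transcript-only and
genome-only alignment gaps, SNP-like mismatches, a non-coding transcript,
and a pseudoautosomal dual placement — together with a truth table of every
injected discrepancy.

## Worked example

```python
import hgvskit as hk

provider = hk.MemoryProvider({"toy": "GCTTTA"})
for s in ["toy:g.3delT", "toy:g.4delT", "toy:g.3_5delTTTinsTT"]:
    print(s, "->", hk.normalize(hk.parse(s), provider))
```

prints

```
toy:g.3delT -> toy:g.5del
toy:g.4delT -> toy:g.5del
toy:g.3_5delTTTinsTT -> toy:g.5del
```

— three spellings of the same deletion converge on the single 3′-most
form. An insertion that repeats its 5′ neighbour is rewritten as a
duplication:

```python
provider = hk.MemoryProvider({"toy": "GCTA"})
print(hk.normalize(hk.parse("toy:g.4_5insA"), provider))
# toy:g.4dup
```

End-to-end projection against a synthetic bundle:

```python
provider, truth = hk.generate_fixture(seed=1)
v = hk.parse("NM_F00002.1:c.26T>C")
g = hk.project_tx_to_genome(v, provider)   # validate -> map -> replace ref -> renormalize
print(g)                                   # NC_F00001.9:g.3048A>G  (minus-strand gene)
print(hk.project_genome_to_tx(g, "NM_F00002.1", provider))  # NM_F00002.1:c.26T>C
```

The genomic spelling carries the complemented alleles, and the round trip
returns the original variant. `hk.c_to_p` predicts protein consequences
(`NP_…:p.(Gly2Arg)`, frameshifts with `fsTer#`, synonymous `p.(Xaa#=)`).

A `hgvskit` console command exposes the same operations over JSON-lines
batches (`parse`, `validate`, `normalize`, `project`, `gen-fixture`); see
`hgvskit --help`.

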