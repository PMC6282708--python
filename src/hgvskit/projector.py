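"""High-level projection pipelines across an assembly.

These compose the low-level coordinate maps into the safe end-to-end
operations a caller actually wants:

* validation happens *before* projection, so coordinates are never
  extrapolated beyond the transcript or alignment;
* the reference allele is replaced from the target sequence *after*
  projection (transcript-genome substitution discrepancies are resolved in
  favour of the target sequence);
* the variant is renormalized on the target sequence, because a placement
  that is 3'-most on one strand generally is not on the other.

Pseudoautosomal transcripts carry two genomic placements; ``par_choice``
selects which chromosome ("X" by default) receives transcript variants.
"""

from __future__ import annotations

from . import mapper as _mapper
from .exceptions import HgvsError, HgvsValidationError
from .normalizer import Normalizer
from .protein import c_to_p
from .provider import DataProvider
from .validation import validate
from .variant import SequenceVariant


def relevant_transcripts(variant_g: SequenceVariant,
                         provider: DataProvider) -> list[str]:
    """Accessions of all transcripts whose aligned genomic span contains the
    variant interval, in deterministic (lexicographic) order."""
    iv = variant_g.posedit.interval
    records = provider.get_transcripts_for_region(
        variant_g.ac, iv.start.base - 1, iv.end.base
    )
    return sorted(r.tx_ac for r in records)


def project_tx_to_genome(variant: SequenceVariant, provider: DataProvider,
                         par_choice: str = "X",
                         normalize: bool = True) -> SequenceVariant:
    """Project a c./n. variant to the genome: validate → (c→n) → n→g with
    gap handling and reference replacement → renormalize on the genome."""
    if variant.type not in ("c", "n"):
        raise HgvsError(f"expected a transcript variant, got {variant.type}.")
    report = validate(variant, provider)
    if report.overall == "ERROR":
        raise HgvsValidationError(
            f"refusing to project invalid variant {variant}: "
            + "; ".join(report.messages("ERROR"))
        )
    record = provider.get_transcript(variant.ac)
    var_n = _mapper.c_to_n(variant, record) if variant.type == "c" else variant
    placement = record.placement_for(par_choice=par_choice)
    var_g = _mapper.n_to_g(var_n, record, provider, placement)
    if normalize:
        var_g = Normalizer(provider, validate_first=False).normalize(var_g)
    return var_g


def project_genome_to_tx(variant_g: SequenceVariant, tx_ac: str,
                         provider: DataProvider,
                         normalize: bool = True) -> SequenceVariant:
    """Project a g. variant onto a transcript: validate → g→n with gap
    handling and reference replacement → renormalize in transcript context
    → c. coordinates when the transcript codes."""
    report = validate(variant_g, provider)
    if report.overall == "ERROR":
        raise HgvsValidationError(
            f"refusing to project invalid variant {variant_g}: "
            + "; ".join(report.messages("ERROR"))
        )
    record = provider.get_transcript(tx_ac)
    placement = record.placement_for(g_ac=variant_g.ac)
    var_n = _mapper.g_to_n(variant_g, record, provider, placement)
    iv = var_n.posedit.interval
    if normalize and not (iv.start.offset or iv.end.offset):
        var_n = Normalizer(provider, validate_first=False).normalize(var_n)
    if record.has_cds:
        return _mapper.n_to_c(var_n, record)
    return var_n


def project(variant: SequenceVariant, provider: DataProvider, to: str,
            tx_ac: str | None = None, par_choice: str = "X",
            ) -> SequenceVariant:
    """Dispatch a projection by target coordinate type ∈ {g, n, c, p}."""
    if to == "g":
        return project_tx_to_genome(variant, provider, par_choice=par_choice)
    if to == "p":
        if variant.type != "c":
            raise HgvsError("protein consequences require a c. variant")
        return c_to_p(variant, provider)
    if to in ("n", "c"):
        if variant.type in ("g", "m"):
            if tx_ac is None:
                hits = relevant_transcripts(variant, provider)
                if len(hits) != 1:
                    raise HgvsError(
                        f"specify a transcript; candidates: {hits or 'none'}"
                    )
                tx_ac = hits[0]
            out = project_genome_to_tx(variant, tx_ac, provider)
            record = provider.get_transcript(tx_ac)
            if to == "n" and out.type == "c":
                return _mapper.c_to_n(out, record)
            if to == "c" and out.type == "n":
                return _mapper.n_to_c(out, record)
            return out
        record = provider.get_transcript(variant.ac)
        if to == "n" and variant.type == "c":
            return _mapper.c_to_n(variant, record)
        if to == "c" and variant.type == "n":
            return _mapper.n_to_c(variant, record)
        return variant
    raise HgvsError(f"unknown projection target {to!r}")
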