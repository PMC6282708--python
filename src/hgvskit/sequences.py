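"""Small sequence utilities shared across modules.

Nucleotide reverse-complement and CDS translation are delegated to
Biopython; amino-acid 1-/3-letter conversion uses an explicit table so that
the formatter controls exactly which tokens appear in HGVS strings
(including ``Ter``/``*`` and ``X``).
"""

from __future__ import annotations

from Bio.Seq import Seq

NUCLEOTIDES = "ACGT"

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter", "X": "Xaa", "U": "Sec",
}
AA1 = {three: one for one, three in AA3.items()}


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(cds: str) -> str:
    """Translate a nucleotide string codon-by-codon; trailing partial codons
    are dropped; stops appear as ``*`` and translation does not halt at them.
    """
    usable = len(cds) - len(cds) % 3
    return str(Seq(cds[:usable]).translate())


def aa_to_3(seq1: str) -> str:
    """One-letter amino-acid string to concatenated three-letter tokens."""
    return "".join(AA3[aa] for aa in seq1)


def aa_to_1(tokens: str) -> str:
    """Concatenated three-letter tokens back to a one-letter string."""
    if len(tokens) % 3:
        raise ValueError(f"not a 3-letter amino-acid string: {tokens!r}")
    out = []
    for i in range(0, len(tokens), 3):
        tok = tokens[i:i + 3]
        if tok not in AA1:
            raise ValueError(f"unknown amino-acid token: {tok!r}")
        out.append(AA1[tok])
    return "".join(out)
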