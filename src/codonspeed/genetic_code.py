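"""Genetic-code helpers shared across modules (DNA alphabet, standard code)."""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

DNA = "ACGT"

#: codon (DNA, upper case) -> one-letter amino acid, stop codons excluded
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)

STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)

#: all 61 sense codons in lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: amino acid -> tuple of synonymous codons
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] = AA_TO_CODONS[_aa] + (_codon,)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (upper-cased)."""
    return str(Seq(seq.upper()).reverse_complement())


def translate_cds(cds: str) -> str:
    """Translate a CDS (without requiring a terminal stop) to protein.

    Raises ``ValueError`` for length not divisible by 3, non-ACGT characters,
    or an internal stop codon.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    if set(cds) - set(DNA):
        raise ValueError(f"CDS contains non-ACGT characters: {sorted(set(cds) - set(DNA))}")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    aa = []
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon {codon} at codon {i + 1}")
        aa.append(CODON_TO_AA[codon])
    return "".join(aa)


def codons_of(cds: str) -> list[str]:
    """Split a CDS into codons, dropping a terminal stop if present."""
    cds = cds.upper()
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    return codons
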