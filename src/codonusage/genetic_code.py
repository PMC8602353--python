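"""Standard genetic code with the degeneracy structure used by codon-usage statistics.

The code table itself comes from Biopython's NCBI table 1; this module adds the
views the analyses need: synonymous families, degeneracy classes, the 59 codons
eligible for relative synonymous codon usage (61 sense codons minus the
single-codon amino acids Met/ATG and Trp/TGG), and the five strictly fourfold
degenerate families (Ala, Gly, Pro, Thr, Val) used by parity-rule-2 analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product

from Bio.Data import CodonTable

NUCLEOTIDES = ("A", "T", "G", "C")

#: Three-letter display names keyed by one-letter amino-acid code.
AA_THREE_LETTER = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}

AMINO_ACIDS = tuple(sorted(AA_THREE_LETTER))

#: Amino acids whose codon family is strictly fourfold degenerate.
FOURFOLD_AMINO_ACIDS = ("A", "G", "P", "T", "V")


@dataclass(frozen=True)
class GeneticCode:
    """The standard genetic code organized by synonymous codon family.

    Attributes
    ----------
    codon_to_aa
        Maps each of the 61 sense codons (DNA alphabet) to its one-letter
        amino acid.
    stop_codons
        The three canonical stop codons.
    family_of
        Maps each amino acid to the tuple of its synonymous codons, in
        alphabetical codon order.
    degeneracy_of
        Family size k in {1, 2, 3, 4, 6} per amino acid.
    rscu_codons
        The 59 codons eligible for RSCU (sense codons minus ATG and TGG),
        alphabetical.
    """

    codon_to_aa: dict[str, str]
    stop_codons: tuple[str, ...]
    family_of: dict[str, tuple[str, ...]] = field(init=False)
    degeneracy_of: dict[str, int] = field(init=False)
    rscu_codons: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        families: dict[str, list[str]] = {}
        for codon, aa in self.codon_to_aa.items():
            families.setdefault(aa, []).append(codon)
        object.__setattr__(
            self, "family_of", {aa: tuple(sorted(c)) for aa, c in families.items()}
        )
        object.__setattr__(
            self, "degeneracy_of", {aa: len(c) for aa, c in families.items()}
        )
        eligible = sorted(
            c for c, aa in self.codon_to_aa.items() if self.degeneracy_of[aa] > 1
        )
        object.__setattr__(self, "rscu_codons", tuple(eligible))

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(self.codon_to_aa))

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons


@lru_cache(maxsize=1)
def standard_code() -> GeneticCode:
    """Return the standard (NCBI table 1) genetic code."""
    table = CodonTable.unambiguous_dna_by_id[1]
    codon_to_aa = {}
    for codon in ("".join(p) for p in product("ATGC", repeat=3)):
        if codon in table.stop_codons:
            continue
        codon_to_aa[codon] = table.forward_table[codon]
    return GeneticCode(codon_to_aa=codon_to_aa, stop_codons=tuple(sorted(table.stop_codons)))
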