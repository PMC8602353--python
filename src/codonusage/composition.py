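"""Positional nucleotide composition, entropy bias measures, and skew variants.

Two Shannon-entropy summaries quantify nucleotide usage bias per gene, both in
bits (log base 2):

* the four-outcome entropy H = -sum_i f_i log2 f_i of the nucleotide
  frequencies f_i, computed over the whole coding sequence and separately at
  each of the three codon positions (range 0..2 bits; 2 = uniform usage);
* a three-outcome entropy per nucleotide type, over how that nucleotide
  distributes across the three codon positions (range 0..log2 3; high =
  the base appears evenly at all positions, low = concentrated at one).

Six skew statistics measure compositional asymmetry between base pairs as
(X - Y)/(X + Y): AT (A vs T), GC (G vs C), purine (A vs G), pyrimidine
(T vs C), keto (T vs G) and amino (A vs C), each at whole-gene scope and per
codon position. A skew whose denominator is zero is reported as NaN (missing),
never as 0, so cohort correlations are not dragged toward the null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .genetic_code import NUCLEOTIDES
from .sequence_io import ACGT, CodingSequence

SCOPES = ("overall", "pos1", "pos2", "pos3")
POSITIONAL_SCOPES = ("pos1", "pos2", "pos3")

#: skew type -> (X, Y) in (X - Y)/(X + Y)
SKEW_PAIRS: dict[str, tuple[str, str]] = {
    "AT": ("A", "T"),
    "GC": ("G", "C"),
    "purine": ("A", "G"),
    "pyrimidine": ("T", "C"),
    "keto": ("T", "G"),
    "amino": ("A", "C"),
}
SKEW_TYPES = tuple(SKEW_PAIRS)

LOG2_3 = math.log2(3.0)


@dataclass(frozen=True)
class NucleotideComposition:
    """Exact base counts per scope (overall and the three codon positions).

    Only A/C/G/T characters are counted; an ambiguity character drops its own
    position from the tallies, not the whole triplet.
    """

    counts: Mapping[str, Mapping[str, int]]  # scope -> base -> count

    def count(self, base: str, scope: str = "overall") -> int:
        return self.counts[scope][base]

    def total(self, scope: str = "overall") -> int:
        return sum(self.counts[scope].values())

    def vector(self, scope: str = "overall") -> tuple[int, int, int, int]:
        """Counts in fixed (A, T, G, C) order."""
        return tuple(self.counts[scope][b] for b in NUCLEOTIDES)  # type: ignore[return-value]


@dataclass(frozen=True)
class EntropyProfile:
    """Per-gene entropy summary, all values in bits."""

    H_overall: float
    H_pos1: float
    H_pos2: float
    H_pos3: float
    per_nucleotide: Mapping[str, float]  # NaN where the base is absent


@dataclass(frozen=True)
class SkewProfile:
    """All six skew types at the four scopes; NaN marks an undefined cell."""

    values: Mapping[tuple[str, str], float]  # (skew_type, scope) -> value

    def get(self, skew_type: str, scope: str = "overall") -> float:
        return self.values[(skew_type, scope)]


def nucleotide_composition(seq: CodingSequence) -> NucleotideComposition:
    counts = {scope: {b: 0 for b in NUCLEOTIDES} for scope in SCOPES}
    for i, ch in enumerate(seq.sequence):
        if ch in ACGT:
            counts["overall"][ch] += 1
            counts[POSITIONAL_SCOPES[i % 3]][ch] += 1
    return NucleotideComposition(counts=counts)


def nucleotide_entropy(counts: Sequence[int]) -> float:
    """Shannon entropy (bits) of a nucleotide count vector.

    Zero counts contribute 0 by continuity. All-zero input raises, as the
    distribution is undefined.
    """
    total = sum(counts)
    if total == 0:
        raise ValueError("entropy undefined for all-zero counts")
    if any(c < 0 for c in counts):
        raise ValueError("negative counts")
    h = 0.0
    for c in counts:
        if c > 0:
            f = c / total
            h -= f * math.log2(f)
    return h


def per_nucleotide_positional_entropy(
    comp: NucleotideComposition, nucleotide: str
) -> float:
    """Entropy (bits) of one base's distribution across the three codon positions.

    Returns NaN when the base is absent from the gene (recorded as missing so
    cohort summaries can skip it).
    """
    positional = [comp.count(nucleotide, s) for s in POSITIONAL_SCOPES]
    if sum(positional) == 0:
        return math.nan
    return nucleotide_entropy(positional)


def entropy_profile(comp: NucleotideComposition) -> EntropyProfile:
    """Both entropy measures for one gene."""
    per_nuc = {n: per_nucleotide_positional_entropy(comp, n) for n in NUCLEOTIDES}
    return EntropyProfile(
        H_overall=nucleotide_entropy(comp.vector("overall")),
        H_pos1=nucleotide_entropy(comp.vector("pos1")),
        H_pos2=nucleotide_entropy(comp.vector("pos2")),
        H_pos3=nucleotide_entropy(comp.vector("pos3")),
        per_nucleotide=per_nuc,
    )


def skew(x: int, y: int) -> float:
    """(x - y)/(x + y); NaN when both counts are zero."""
    denom = x + y
    if denom == 0:
        return math.nan
    return (x - y) / denom


def skew_profile(comp: NucleotideComposition) -> SkewProfile:
    values: dict[tuple[str, str], float] = {}
    for skew_type, (x_base, y_base) in SKEW_PAIRS.items():
        for scope in SCOPES:
            values[(skew_type, scope)] = skew(
                comp.count(x_base, scope), comp.count(y_base, scope)
            )
    return SkewProfile(values=values)
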