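"""RSCU, cross-species dispersion (Vs), ENC, GC3 and the expected-ENC curve.

Relative synonymous codon usage (RSCU) for codon c in a synonymous family of
size k with family total T is k * count_c / T; the family mean is 1 and the
family sum equals k. Single-codon amino acids (Met, Trp) and stop codons are
excluded, leaving a 59-dimensional vector. A codon with RSCU 0 whose amino
acid is present is *absent*; a codon whose whole family is unused is
*undefined* (NaN) — the distinction drives the absent-codon cohort report.

Codons with RSCU > 1.6 are classified overrepresented and RSCU < 0.6
underrepresented (strict inequalities; the boundary values are unbiased).

Vs = sigma / x_bar is the coefficient of variation of one codon's RSCU values
across a species cohort (sample standard deviation, denominator N-1); lower
Vs means more conserved usage of that codon across species.

ENC is Wright's effective number of codons: per amino acid with family total
n >= 2, the codon homozygosity F = (n * sum p_i^2 - 1)/(n - 1); class means
F_k over amino acids of degeneracy k (excluding undefined or non-positive F)
give ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, with a missing 3-fold class (Ile)
imputed as (F2 + F4)/2 and finite-sample estimates above 61 truncated to 61.
ENC ranges from 20 (one codon per amino acid) to 61 (uniform usage); values
below 35 mark significant codon usage bias.

The null expectation of ENC when GC content alone drives codon choice is
ENC_exp(s) = 2 + s + 29/(s^2 + (1-s)^2), with s the GC3 fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genetic_code import GeneticCode, standard_code
from .sequence_io import CodonCountTable

RSCU_OVER = 1.6
RSCU_UNDER = 0.6
ENC_SIGNIFICANT = 35.0
ENC_MAX = 61.0
ENC_MIN = 20.0

#: degeneracy class -> number of amino acids in it (standard code, 6-fold kept whole)
DEGENERACY_CLASS_SIZES = {2: 9, 3: 1, 4: 5, 6: 3}


@dataclass(frozen=True)
class RSCUVector:
    """59 RSCU values for one gene plus the absent/undefined codon sets."""

    values: Mapping[str, float]  # codon -> RSCU, NaN when the family is absent
    absent_codons: frozenset[str]
    undefined_codons: frozenset[str]

    def __getitem__(self, codon: str) -> float:
        return self.values[codon]


@dataclass(frozen=True)
class ENCResult:
    enc: float
    gc3: float
    expected_enc: float
    class_homozygosities: Mapping[int, float]  # k -> F_k class mean (NaN if imputed base missing)

    @property
    def significant_bias(self) -> bool:
        return self.enc < ENC_SIGNIFICANT

    @property
    def residual(self) -> float:
        """ENC minus the GC3-driven null expectation; negative = below the curve."""
        return self.enc - self.expected_enc


def rscu(counts: CodonCountTable, code: GeneticCode | None = None) -> RSCUVector:
    """RSCU over the 59 eligible codons.

    Raises
    ------
    ValueError
        If the gene contains no sense codon at all.
    """
    code = code or standard_code()
    if sum(counts.counts[c] for c in code.sense_codons) == 0:
        raise ValueError("no sense codons: RSCU undefined")
    values: dict[str, float] = {}
    absent: set[str] = set()
    undefined: set[str] = set()
    for aa, family in code.family_of.items():
        k = code.degeneracy_of[aa]
        if k == 1:
            continue
        family_total = sum(counts.counts[c] for c in family)
        for codon in family:
            if family_total == 0:
                values[codon] = math.nan
                undefined.add(codon)
            else:
                values[codon] = k * counts.counts[codon] / family_total
                if counts.counts[codon] == 0:
                    absent.add(codon)
    return RSCUVector(
        values=values,
        absent_codons=frozenset(absent),
        undefined_codons=frozenset(undefined),
    )


def classify_rscu(value: float) -> str:
    """Bias class of one RSCU value: strict thresholds at 0.6 and 1.6."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "undefined"
    if value < 0:
        raise ValueError(f"RSCU cannot be negative: {value}")
    if value == 0:
        return "absent"
    if value > RSCU_OVER:
        return "overrepresented"
    if value < RSCU_UNDER:
        return "underrepresented"
    return "unbiased"


def absent_codon_report(
    cohort: Iterable[tuple[str, RSCUVector]], code: GeneticCode | None = None
) -> pd.DataFrame:
    """Which species never use an eligible codon while using its amino acid.

    Returns one row per codon that is absent somewhere: codon, amino acid,
    n_species and the semicolon-free species list. Species missing the whole
    amino-acid family are not listed (their usage is undefined, not zero).
    """
    code = code or standard_code()
    rows = []
    by_codon: dict[str, list[str]] = {c: [] for c in code.rscu_codons}
    for species, vec in cohort:
        for codon in vec.absent_codons:
            by_codon[codon].append(species)
    for codon in code.rscu_codons:
        if by_codon[codon]:
            rows.append(
                {
                    "codon": codon,
                    "amino_acid": code.codon_to_aa[codon],
                    "n_species": len(by_codon[codon]),
                    "species": ", ".join(by_codon[codon]),
                }
            )
    return pd.DataFrame(rows, columns=["codon", "amino_acid", "n_species", "species"])


def vs_dispersion(
    cohort_rscu: pd.DataFrame, code: GeneticCode | None = None
) -> pd.DataFrame:
    """Cross-species dispersion Vs = sigma/x_bar per codon.

    Parameters
    ----------
    cohort_rscu
        Species-by-codon matrix of RSCU values (NaN = undefined; such cells
        are skipped pairwise and counted in ``n_missing``).

    Returns
    -------
    DataFrame indexed like a 59-row table: codon, amino_acid, vs, mean_rscu,
    sd_rscu, n_species, n_missing. Vs is NaN when fewer than two species have
    a defined value or the mean is 0.
    """
    code = code or standard_code()
    rows = []
    for codon in code.rscu_codons:
        col = cohort_rscu[codon] if codon in cohort_rscu.columns else pd.Series(dtype=float)
        defined = col.dropna()
        n = len(defined)
        mean = float(defined.mean()) if n else math.nan
        sd = float(defined.std(ddof=1)) if n >= 2 else math.nan
        if n >= 2 and mean > 0:
            vs = sd / mean
        else:
            vs = math.nan
        rows.append(
            {
                "codon": codon,
                "amino_acid": code.codon_to_aa[codon],
                "vs": vs,
                "mean_rscu": mean,
                "sd_rscu": sd,
                "n_species": n,
                "n_missing": len(col) - n if len(col) else 0,
            }
        )
    return pd.DataFrame(rows)


def _synonymous_third_position_codons(code: GeneticCode) -> tuple[str, ...]:
    """Sense codons whose third position enters GC3 (ATG/TGG excluded)."""
    return code.rscu_codons


def gc3(counts: CodonCountTable, code: GeneticCode | None = None) -> float:
    """G+C fraction at the third position of synonymously-coded sense codons.

    ATG, TGG and stop codons are excluded: their third position carries no
    synonymous choice.
    """
    code = code or standard_code()
    eligible = _synonymous_third_position_codons(code)
    total = sum(counts.counts[c] for c in eligible)
    if total == 0:
        raise ValueError("no synonymous codons: GC3 undefined")
    gc = sum(counts.counts[c] for c in eligible if c[2] in "GC")
    return gc / total


def codon_homozygosity(family_counts: Sequence[int]) -> float:
    """Wright's F for one amino-acid family; NaN when n < 2."""
    n = sum(family_counts)
    if n < 2:
        return math.nan
    p = np.asarray(family_counts, dtype=float) / n
    return (n * float(np.sum(p * p)) - 1.0) / (n - 1.0)


def enc(counts: CodonCountTable, code: GeneticCode | None = None) -> ENCResult:
    """Wright's effective number of codons for one gene.

    Raises
    ------
    ValueError
        When a required degeneracy class (2-, 4- or 6-fold) has no family
        with a defined positive homozygosity; the message names the classes.
    """
    code = code or standard_code()
    f_by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, family in code.family_of.items():
        k = code.degeneracy_of[aa]
        if k == 1:
            continue
        f = codon_homozygosity([counts.counts[c] for c in family])
        if not math.isnan(f) and f > 0:
            f_by_class[k].append(f)
    f_bar = {
        k: (sum(v) / len(v) if v else math.nan) for k, v in f_by_class.items()
    }
    missing_required = [k for k in (2, 4, 6) if math.isnan(f_bar[k])]
    if missing_required:
        raise ValueError(
            f"ENC not estimable: no usable family in degeneracy class(es) "
            f"{missing_required}"
        )
    f3 = f_bar[3]
    if math.isnan(f3):
        f3 = (f_bar[2] + f_bar[4]) / 2.0  # Ile absent: standard imputation
    raw = 2.0 + 9.0 / f_bar[2] + 1.0 / f3 + 5.0 / f_bar[4] + 3.0 / f_bar[6]
    value = min(raw, ENC_MAX)
    s = gc3(counts, code)
    return ENCResult(
        enc=value,
        gc3=s,
        expected_enc=expected_enc(s),
        class_homozygosities={2: f_bar[2], 3: f_bar[3], 4: f_bar[4], 6: f_bar[6]},
    )


def expected_enc(s: float) -> float:
    """Null ENC when GC compositional constraint alone drives codon usage."""
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"GC3 fraction must be in [0, 1], got {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)
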