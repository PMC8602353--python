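"""Cohort-level mutation-vs-selection diagnostics.

* Parity-rule-2 (PR2) coordinates: AT-bias A3/(A3+T3) and GC-bias
  G3/(G3+C3) from third-position counts pooled over the five strictly
  fourfold-degenerate families (Ala, Gly, Pro, Thr, Val). Under no
  strand-specific mutation/selection asymmetry both coordinates sit at 0.5.
* The ENC-vs-GC3 table with residuals against the null curve; genes below
  the curve (negative residual) are read as selection-dominated.
* Overall-vs-positional skew correlations: for each of the six skew types,
  Pearson r (two-tailed p) between a gene's whole-sequence skew and its skew
  at each codon position, across the cohort.
* PCA of codon usage (59-dim RSCU) or amino-acid usage (20-dim frequency)
  vectors, one point per gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .codon_metrics import ENCResult, enc
from .composition import SKEW_TYPES, SkewProfile
from .genetic_code import FOURFOLD_AMINO_ACIDS, GeneticCode, standard_code
from .sequence_io import CodonCountTable

FeatureSpace = Literal["rscu59", "aa20"]


@dataclass(frozen=True)
class PR2Point:
    """Third-position composition of the fourfold families for one gene."""

    a3: int
    t3: int
    g3: int
    c3: int

    @property
    def at_bias(self) -> float:
        denom = self.a3 + self.t3
        return self.a3 / denom if denom else math.nan

    @property
    def gc_bias(self) -> float:
        denom = self.g3 + self.c3
        return self.g3 / denom if denom else math.nan


@dataclass(frozen=True)
class PCAResult:
    coordinates: pd.DataFrame        # genes x components, zero column means
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame           # features x components
    feature_space: FeatureSpace
    column_means: pd.Series          # means used for centering (after imputation)


def pr2_point(counts: CodonCountTable, code: GeneticCode | None = None) -> PR2Point:
    """Pool third-position bases over Ala+Gly+Pro+Thr+Val codons only."""
    code = code or standard_code()
    tallies = {"A": 0, "T": 0, "G": 0, "C": 0}
    for aa in FOURFOLD_AMINO_ACIDS:
        for codon in code.family_of[aa]:
            tallies[codon[2]] += counts.counts[codon]
    return PR2Point(a3=tallies["A"], t3=tallies["T"], g3=tallies["G"], c3=tallies["C"])


def enc_gc3_table(
    cohort: Iterable[tuple[str, CodonCountTable]], code: GeneticCode | None = None
) -> pd.DataFrame:
    """Per-gene ENC, GC3, expected ENC and residual (ENC - expected).

    Genes whose ENC is not estimable appear with NaN statistics rather than
    being dropped.
    """
    code = code or standard_code()
    rows = []
    for gene_id, counts in cohort:
        try:
            r: ENCResult = enc(counts, code)
            rows.append(
                {
                    "id": gene_id,
                    "gc3": r.gc3,
                    "enc": r.enc,
                    "expected_enc": r.expected_enc,
                    "residual": r.residual,
                    "significant_bias": r.significant_bias,
                }
            )
        except ValueError:
            rows.append(
                {
                    "id": gene_id,
                    "gc3": math.nan,
                    "enc": math.nan,
                    "expected_enc": math.nan,
                    "residual": math.nan,
                    "significant_bias": None,
                }
            )
    return pd.DataFrame(rows)


def _significance_label(p: float) -> str:
    if math.isnan(p):
        return "NA"
    if p < 0.001:
        return "***"
    if p > 0.05:
        return "NS"
    return "*"


def skew_correlation_table(profiles: Sequence[SkewProfile]) -> pd.DataFrame:
    """Pearson correlations of overall vs positional skew, per type and position.

    Returns 18 rows (6 skew types x positions 1-3) with r, the two-tailed
    p-value from the t transform with n-2 degrees of freedom, the number of
    genes with both values defined, and a significance label (*** p<0.001,
    NS p>0.05). Cells with fewer than 3 usable genes, or a constant column,
    yield NaN r.
    """
    rows = []
    for skew_type in SKEW_TYPES:
        overall = np.array([p.get(skew_type, "overall") for p in profiles])
        for pos in (1, 2, 3):
            positional = np.array([p.get(skew_type, f"pos{pos}") for p in profiles])
            mask = ~(np.isnan(overall) | np.isnan(positional))
            x, y = overall[mask], positional[mask]
            n = int(mask.sum())
            if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                r, p_val = math.nan, math.nan
            else:
                r, p_val = stats.pearsonr(x, y)
            rows.append(
                {
                    "skew_type": skew_type,
                    "position": pos,
                    "r": float(r) if not math.isnan(r) else math.nan,
                    "p_value": float(p_val) if not math.isnan(p_val) else math.nan,
                    "n": n,
                    "significance": _significance_label(p_val),
                }
            )
    return pd.DataFrame(rows)


def pca_usage(
    matrix: pd.DataFrame,
    feature_space: FeatureSpace = "rscu59",
    n_components: int | None = None,
) -> PCAResult:
    """PCA of per-gene usage vectors (rows = genes, columns = features).

    Undefined entries (NaN, e.g. RSCU of an absent amino-acid family) are
    imputed with the feature's cohort mean before centering, which leaves the
    column means unchanged. Values are not rescaled: RSCU is already
    family-normalized and amino-acid frequencies share a common scale.

    Raises
    ------
    ValueError
        With fewer than 2 genes, or when a feature is undefined in every gene.
    """
    if len(matrix) < 2:
        raise ValueError("PCA requires at least 2 genes")
    filled = matrix.astype(float).copy()
    col_means = filled.mean(axis=0, skipna=True)
    if col_means.isna().any():
        bad = list(col_means.index[col_means.isna()])
        raise ValueError(f"features undefined in every gene: {bad}")
    filled = filled.fillna(col_means)
    max_rank = min(len(filled) - 1, filled.shape[1])
    k = max_rank if n_components is None else min(n_components, max_rank)
    pca = PCA(n_components=k)
    coords = pca.fit_transform(filled.to_numpy())
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        coordinates=pd.DataFrame(coords, index=matrix.index, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=pd.DataFrame(
            pca.components_.T, index=matrix.columns, columns=comp_names
        ),
        feature_space=feature_space,
        column_means=col_means,
    )


def rscu_matrix(
    cohort: Iterable[tuple[str, Mapping[str, float]]],
    code: GeneticCode | None = None,
) -> pd.DataFrame:
    """Stack per-gene RSCU mappings into a genes x 59 DataFrame."""
    code = code or standard_code()
    ids, rows = [], []
    for gene_id, values in cohort:
        ids.append(gene_id)
        rows.append([values[c] for c in code.rscu_codons])
    return pd.DataFrame(rows, index=ids, columns=list(code.rscu_codons))
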