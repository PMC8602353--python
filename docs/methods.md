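# Methods

This note documents the statistical model behind each pipeline stage, the
conventions adopted where the underlying definitions admit more than one
reading, and what the synthetic cohorts do and do not emulate.

## Sequence layer

A coding sequence is an in-frame string over {A,C,G,T}, length a multiple of
three; RNA input is accepted (U→T) and case-normalized. The terminal stop
codon, when present, is **kept** in the sequence: nucleotide-level statistics
(composition, entropy, skews) run on the whole coding sequence, while
codon-level statistics (RSCU, ENC, GC3, PR2, amino-acid frequencies) exclude
stop codons. This keeps the two layers independent; whether a user's FASTA
includes terminal stops therefore shifts nucleotide statistics marginally
(one codon in hundreds) and codon statistics not at all.

Validation distinguishes hard errors (empty record, frameshifted length)
from warnings (non-ACGT characters, internal stop codons). In lenient mode a
trailing incomplete triplet is trimmed with a logged warning; ambiguity
characters are tolerated — the containing codon is excluded from codon
counts (tallied separately), but its resolvable A/C/G/T positions still
count toward nucleotide composition, so one N costs one position, not three.
Internal stops count toward nucleotide statistics and the stop tally only.

## Entropy measures

Both measures are Shannon entropies in bits (log₂ throughout; 0·log₂0 := 0
by continuity).

1. **Base-usage entropy** H = −Σᵢ fᵢ log₂ fᵢ over the four nucleotide
   frequencies, computed overall and per codon position (range 0–2 bits).
   Because frequencies are ratios of counts, H is invariant to codon order
   and to duplicating the gene.
2. **Per-nucleotide positional entropy**: for one base n, the three-outcome
   entropy of its distribution across codon positions,
   fₚ = count(n, pos p) / Σₚ count(n, pos p), range 0–log₂3 ≈ 1.585 bits.
   The denominator is the count of that *specific* base summed over the
   three positions — the only reading under which the fₚ form a probability
   distribution and the measure differs from (1). A base absent from the
   gene yields an undefined (NaN) entropy, recorded rather than raised so
   cohort summaries can skip it.

Entropies are kept at full float precision internally; TSV output rounds to
6 decimals.

## Skews

Six pairwise asymmetries (X−Y)/(X+Y): AT (A vs T), GC (G vs C), purine
(A vs G), pyrimidine (T vs C), keto (T vs G), amino (A vs C), each at
whole-gene scope and at positions 1–3 (24 cells per gene). A zero
denominator yields NaN, never 0 — encoding "no data" as "no skew" would bias
cohort correlations toward the null. Reverse-complementing a clean sequence
negates overall AT and GC skew, which the property suite checks.

## RSCU, classification, Vs

For codon c in a family of size k with family total T:
RSCU_c = k·n_c/T. Met (ATG), Trp (TGG) and stops are excluded, leaving 59
dimensions; each present family sums to k (mean 1). Two kinds of "no value"
are kept distinct: **absent** (n_c = 0 but the amino acid is used — a real
avoidance signal) versus **undefined** (the whole family is unused — NaN, no
signal). The absent-codon cohort report lists, per codon, the species with a
genuine zero; species lacking the amino acid entirely are not listed.

Classification uses strict inequalities — RSCU > 1.6 overrepresented,
RSCU < 0.6 underrepresented — so the boundary values are unbiased.

Vs = σ/x̄ per codon across the cohort, with σ the sample standard deviation
(denominator N−1) over species whose value is defined (pairwise deletion;
the per-codon missing count is reported). Vs is undefined for N < 2 or
x̄ = 0.

## ENC and the null curve

Wright's estimator. Per amino acid with family total n ≥ 2 and codon
proportions pᵢ, the homozygosity F = (n·Σpᵢ² − 1)/(n − 1); the class means
F̄ₖ average F over amino acids of degeneracy k ∈ {2, 3, 4, 6} (families with
n < 2 or F ≤ 0 are excluded from their class mean); then

ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆

with F̄₃ (Ile alone) imputed as (F̄₂ + F̄₄)/2 when unestimable, and estimates
above 61 truncated to 61. The three sixfold amino acids (Leu, Ser, Arg) are
treated as single 6-codon families, consistent with the 20–61 range. A gene
in which a required class (2-, 4- or 6-fold) has no usable family raises an
error naming the classes; the pipeline records such genes with NA rather
than aborting the cohort. ENC < 35 flags significant bias (strict
inequality).

GC3 is the G+C fraction at the third position of the 59 synonymously-coded
sense codons — ATG, TGG and stops are excluded because their third position
carries no synonymous choice.

The null curve ENC_exp(s) = 2 + s + 29/(s² + (1−s)²) gives the ENC expected
when GC compositional constraint alone drives codon choice; the per-gene
residual ENC − ENC_exp(GC3) is negative for genes below the curve
(selection-dominated reading). The curve's compositional term is symmetric
in s ↔ 1−s; the small +s term is part of the standard form and is kept.

## PR2

Third-position counts are pooled over the five strictly fourfold families
only (Ala, Gly, Pro, Thr, Val) — the fourfold *subsets* of the sixfold
Leu/Ser/Arg families are excluded, so the coordinates are not confounded by
first/second-position choices within those families. AT-bias = A₃/(A₃+T₃),
GC-bias = G₃/(G₃+C₃); a zero denominator gives NaN. The point is invariant
to codon order and count scaling.

## Skew correlations

For each skew type and position, Pearson r between overall and positional
skew across genes (genes are the statistical unit: one gene per species),
with the two-tailed p from the exact t transform at n−2 degrees of freedom.
Cells use pairwise deletion of NaN skews and report n; fewer than 3 usable
genes or a constant column gives NaN. Significance labels follow the
per-cell convention *** (p < 0.001), NS (p > 0.05), * otherwise; no
multiple-testing correction is applied — a reporting convention, not an
endorsement.

## PCA

Column-mean-centered PCA (singular value decomposition of the centered
matrix) on raw RSCU values or amino-acid frequencies — no z-scoring, since
RSCU is already family-normalized and frequencies share one scale. NaN
entries (undefined families) are imputed with the feature's cohort mean
before centering, which preserves column means and avoids dropping species;
with no missing data this is a no-op. All components up to
min(genes−1, features) are available; the pipeline writes the first 2 by
default. Projecting coordinates through the loadings and adding back the
column means reconstructs the imputed matrix (checked to 1e-8); explained
variance ratios agree with a direct covariance eigendecomposition.

## Synthetic cohorts

`generate_cohort` emulates a cohort of orthologous CDS: every species draws
a protein of fixed length from a shared amino-acid profile, then
back-translates it under species-specific codon preferences, appending a
TAA stop (configurable; excluded from ground-truth probabilities).

* Default profile: Ser mass 0.12 (a serine-rich protein family), Met and
  Trp fixed at 0.02 each, the remaining 17 amino acids uniform over the
  leftover 0.84. Default shape: 226 species × 500 codons (~1.5 kb), the
  scale of a typical single-gene eukaryote-wide cohort.
* **Mutation pressure**: within-family codon probability ∝ product of base
  probabilities θ over the family's varying positions. Boundary θ (a base
  mass exactly 0) is resolved as the limit of the interior model: the
  family's codons with fewest zero factors survive, weighted by their
  nonzero factors. `gc3_calibrate` finds the symmetric θ (A=T, G=C) whose
  expected GC3 matches a target, by Brent root-finding to 1e-6; the
  expectation is taken over the default amino-acid profile, so calibration
  is exact in expectation and realized GC3 converges with length.
* **Selection**: per-family preferences drawn from a symmetric Dirichlet;
  concentration → ∞ recovers uniform usage (ENC → 61), concentration ≪ 1
  concentrates mass on one codon per family (ENC → 20). Mean ENC is
  monotone decreasing in selection strength.
* **Mixed**: per-family probability ∝ mut^(1−λ)·sel^λ, λ ∈ [0, 1]
  (default 0.5), a log-linear interpolation.

Randomness: one integer seed per cohort; species substreams are keyed by
(seed, species index), so a species' sequence is independent of cohort size
and generation order, and identical seeds give byte-identical FASTA.

What the generator does **not** emulate: phylogenetic correlation between
species (all species are exchangeable draws), indels and length variation,
intron/exon structure, context-dependent mutation (e.g. CpG effects), and
within-gene heterogeneity of codon preference. Passing tests on synthetic
cohorts therefore validate the estimators' arithmetic and their qualitative
mutation-vs-selection contrasts (curve-tracking vs below-curve ENC, PR2
centering under symmetric θ, positional skew correlations under a GC3
gradient), not claims about any real gene family.

## Problem sizes used in the test and acceptance suites

Chosen as the smallest sizes at which the checked effects are comfortably
larger than sampling noise: GC3 recovery at 2000 codons (binomial error
≈ 0.005 per gene); ENC monotonicity over five Dirichlet concentrations at
8 × 800 codons; curve-tracking vs below-curve contrast at 10 × 1000 codons
per condition; the GC3-gradient skew-correlation ordering over 24 genes of
600 codons spanning GC3 targets 0.25–0.75. Property suites run a few hundred
randomized instances each.

## Numerical conventions

Missing values are NaN in memory and `NA` in every TSV. Output tables are
written in input order with fixed 6-decimal formatting, so identical input
and configuration reproduce identical bytes. Thresholds (0.6/1.6 RSCU,
ENC 35) are strict inequalities. Skipped genes are accounted for explicitly:
analyzed + skipped = input records.
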