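"""Synthetic orthologous-CDS cohorts with known codon-usage structure.

The generator emulates a cohort of orthologous coding sequences of similar
length that share a conserved amino-acid profile while each species applies
its own synonymous-codon preferences. Two bias mechanisms are modelled:

* ``mutation_pressure`` — codon probabilities within each synonymous family
  follow a product of per-base probabilities ``theta`` (position-independent
  compositional pressure), renormalized within the family. With A=T and G=C
  this reproduces the PR2 null; sweeping the G+C mass traces the expected
  ENC-vs-GC3 curve.
* ``selection`` — each species draws per-family codon preferences from a
  symmetric Dirichlet with a concentration parameter; small concentrations
  give strongly skewed (translationally selected) preferences and depress
  ENC below the compositional expectation.
* ``mixed`` — per-family probabilities proportional to
  mut^(1-lambda) * sel^lambda, a log-linear interpolation between the two.

Every cohort is reproducible from its seed: species substreams are keyed by
(seed, species index), so one species' sequence does not depend on how many
others were generated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np
from scipy.optimize import brentq

from .genetic_code import AMINO_ACIDS, GeneticCode, standard_code
from .sequence_io import CodingSequence

BiasModel = Literal["mutation_pressure", "selection", "mixed"]

#: Default amino-acid profile: serine-rich (mass 0.12) with small fixed
#: Met/Trp mass, remaining amino acids uniform. Mimics a Ser-rich protein of
#: the kind the cohort stands in for.
_SER_MASS = 0.12
_MET_TRP_MASS = 0.02


def default_aa_profile() -> dict[str, float]:
    rest = (1.0 - _SER_MASS - 2 * _MET_TRP_MASS) / 17.0
    profile = {}
    for aa in AMINO_ACIDS:
        if aa == "S":
            profile[aa] = _SER_MASS
        elif aa in ("M", "W"):
            profile[aa] = _MET_TRP_MASS
        else:
            profile[aa] = rest
    return profile


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generative parameters for one synthetic cohort.

    Defaults describe the reference cohort the pipeline is exercised on:
    226 species, 500-codon proteins (~1500 nt with the terminal stop),
    compositionally neutral mutation pressure.
    """

    n_species: int = 226
    protein_length: int = 500
    bias_model: BiasModel = "mutation_pressure"
    theta: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)  # A,T,G,C
    concentration: float = 1.0
    mix_lambda: float = 0.5
    gc3_target: float | None = None
    stop_codon: str = "TAA"
    aa_profile: Mapping[str, float] = field(default_factory=default_aa_profile)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.protein_length < 1:
            raise ValueError("protein_length must be >= 1")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if not math.isclose(sum(self.theta), 1.0, abs_tol=1e-9):
            raise ValueError("theta must sum to 1")
        if not math.isclose(sum(self.aa_profile.values()), 1.0, abs_tol=1e-9):
            raise ValueError("aa_profile must sum to 1")
        if not 0.0 <= self.mix_lambda <= 1.0:
            raise ValueError("mix_lambda must be in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually used, for parameter-recovery tests."""

    spec: SyntheticCohortSpec
    codon_probs: Mapping[str, Mapping[str, Mapping[str, float]]]  # species -> aa -> codon -> p
    realized_gc3: Mapping[str, float]


def mutation_pressure_codon_probs(
    theta: tuple[float, float, float, float], code: GeneticCode | None = None
) -> dict[str, dict[str, float]]:
    """Per-family codon probabilities under compositional pressure theta.

    P(codon b1 b2 b3) is proportional to theta[b1] * theta[b2] * theta[b3],
    renormalized within each synonymous family. A theta on the boundary of
    the simplex (some base mass exactly 0) is handled as the limit of the
    interior model: within each family only the codons with the fewest
    zero-probability positions survive, weighted by the product of their
    nonzero factors. For strictly positive theta this reduces to the plain
    renormalized product.
    """
    if any(t < 0 for t in theta):
        raise ValueError(f"theta must be non-negative, got {theta}")
    if sum(theta) == 0:
        raise ValueError("theta has zero total mass")
    code = code or standard_code()
    base_p = dict(zip("ATGC", theta))
    out: dict[str, dict[str, float]] = {}
    for aa, family in code.family_of.items():
        # positions shared by the whole family cancel in the renormalization
        varying = [i for i in range(3) if len({c[i] for c in family}) > 1]
        n_zero = {c: sum(base_p[c[i]] == 0 for i in varying) for c in family}
        fewest = min(n_zero.values())
        weights = {
            c: (
                math.prod(base_p[c[i]] for i in varying if base_p[c[i]] > 0)
                if n_zero[c] == fewest
                else 0.0
            )
            for c in family
        }
        total = sum(weights.values())
        out[aa] = {c: w / total for c, w in weights.items()}
    return out


def selection_codon_probs(
    concentration: float,
    code: GeneticCode | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, dict[str, float]]:
    """Per-family preferences drawn from a symmetric Dirichlet.

    Smaller concentration -> more skewed preferences (stronger selection for
    one codon per family); concentration -> infinity recovers uniform usage.
    """
    code = code or standard_code()
    rng = rng if rng is not None else np.random.default_rng()
    out: dict[str, dict[str, float]] = {}
    for aa in sorted(code.family_of):
        family = code.family_of[aa]
        k = len(family)
        if k == 1:
            out[aa] = {family[0]: 1.0}
            continue
        p = rng.dirichlet(np.full(k, concentration))
        out[aa] = dict(zip(family, p.tolist()))
    return out


def _mixed_codon_probs(
    mut: Mapping[str, Mapping[str, float]],
    sel: Mapping[str, Mapping[str, float]],
    lam: float,
) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for aa, family in mut.items():
        weights = {
            c: (family[c] ** (1.0 - lam)) * (sel[aa][c] ** lam) for c in family
        }
        total = sum(weights.values())
        out[aa] = {c: w / total for c, w in weights.items()}
    return out


def _species_rng(seed: int, index: int) -> np.random.Generator:
    # keyed substream: independent of cohort size and generation order
    return np.random.default_rng([seed, index])


def generate_cohort(
    spec: SyntheticCohortSpec, code: GeneticCode | None = None
) -> tuple[list[CodingSequence], GroundTruth]:
    """Generate one cohort of coding sequences plus its ground truth.

    Each species draws codon preferences per the bias model, samples a
    protein from the shared amino-acid profile, back-translates it by
    sampling codons from its own preferences, and appends the stop codon.
    """
    code = code or standard_code()
    theta = spec.theta
    if spec.gc3_target is not None:
        theta = gc3_calibrate(spec.gc3_target, code, spec.aa_profile)
    mut_probs = mutation_pressure_codon_probs(theta, code)
    aas = sorted(spec.aa_profile)
    aa_p = np.array([spec.aa_profile[a] for a in aas])

    seqs: list[CodingSequence] = []
    all_probs: dict[str, dict[str, dict[str, float]]] = {}
    realized_gc3: dict[str, float] = {}
    for i in range(spec.n_species):
        rng = _species_rng(spec.seed, i)
        if spec.bias_model == "mutation_pressure":
            probs = mut_probs
        elif spec.bias_model == "selection":
            probs = selection_codon_probs(spec.concentration, code, rng)
        else:
            sel = selection_codon_probs(spec.concentration, code, rng)
            probs = _mixed_codon_probs(mut_probs, sel, spec.mix_lambda)
        protein = rng.choice(aas, size=spec.protein_length, p=aa_p)
        # inverse-CDF codon sampling per amino acid (fast path for long genes)
        cum = {
            aa: np.cumsum([probs[aa][c] for c in code.family_of[aa]]) for aa in aas
        }
        u = rng.random(spec.protein_length)
        codons = []
        for aa, ui in zip(protein, u):
            fam = code.family_of[aa]
            j = int(np.searchsorted(cum[aa], ui, side="right"))
            codons.append(fam[min(j, len(fam) - 1)])
        sequence = "".join(codons) + spec.stop_codon
        name = f"synthetic_{i:04d}"
        seqs.append(CodingSequence(id=name, species=name, sequence=sequence))
        all_probs[name] = {aa: dict(fam) for aa, fam in probs.items()}
        third = [c[2] for c, aa in zip(codons, protein) if code.degeneracy_of[aa] > 1]
        realized_gc3[name] = (
            sum(b in "GC" for b in third) / len(third) if third else math.nan
        )
    truth = GroundTruth(
        spec=replace(spec, theta=theta),
        codon_probs=all_probs,
        realized_gc3=realized_gc3,
    )
    return seqs, truth


def expected_gc3(
    theta: tuple[float, float, float, float],
    code: GeneticCode | None = None,
    aa_profile: Mapping[str, float] | None = None,
) -> float:
    """Expected GC3 of a mutation-pressure gene with the given amino-acid profile.

    GC3 is defined over synonymously-coded sense codons (Met/Trp excluded),
    matching the analysis-side definition.
    """
    code = code or standard_code()
    aa_profile = aa_profile or default_aa_profile()
    probs = mutation_pressure_codon_probs(theta, code)
    num = 0.0
    den = 0.0
    for aa, mass in aa_profile.items():
        if code.degeneracy_of[aa] == 1:
            continue
        den += mass
        num += mass * sum(
            p for c, p in probs[aa].items() if c[2] in "GC"
        )
    return num / den


def gc3_calibrate(
    gc3_target: float,
    code: GeneticCode | None = None,
    aa_profile: Mapping[str, float] | None = None,
) -> tuple[float, float, float, float]:
    """Find theta with A=T, G=C whose expected GC3 matches the target.

    Solves expected_gc3(theta(g)) = gc3_target for the G+C mass g by Brent's
    method to 1e-6. Raises when the target lies outside the attainable range.
    """
    if not 0.0 < gc3_target < 1.0:
        raise ValueError("gc3_target must be strictly between 0 and 1")
    code = code or standard_code()
    aa_profile = aa_profile or default_aa_profile()

    def theta_of(g: float) -> tuple[float, float, float, float]:
        return ((1 - g) / 2, (1 - g) / 2, g / 2, g / 2)

    def f(g: float) -> float:
        return expected_gc3(theta_of(g), code, aa_profile) - gc3_target

    eps = 1e-9
    lo, hi = f(eps), f(1 - eps)
    if not lo < 0 < hi:
        raise ValueError(
            f"gc3_target {gc3_target} outside attainable range "
            f"[{lo + gc3_target:.6f}, {hi + gc3_target:.6f}]"
        )
    g = brentq(f, eps, 1 - eps, xtol=1e-6)
    return theta_of(float(g))
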