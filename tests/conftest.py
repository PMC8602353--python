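import numpy as np
import pytest

from codonusage import CodonCountTable, SyntheticCohortSpec, generate_cohort, standard_code


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture(scope="session")
def counts_from(code):
    """Build a CodonCountTable from a sparse {codon: count} mapping."""

    def _build(mapping):
        counts = {c: 0 for c in list(code.sense_codons) + list(code.stop_codons)}
        counts.update(mapping)
        return CodonCountTable(counts=counts)

    return _build


@pytest.fixture(scope="session")
def small_cohort():
    """12 mutation-pressure genes of 300 codons, fixed seed."""
    spec = SyntheticCohortSpec(n_species=12, protein_length=300, seed=11)
    seqs, truth = generate_cohort(spec)
    return seqs, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
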