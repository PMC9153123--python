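import numpy as np
import pytest

from codonshift.codon_core import CodonFamilyTable, ParameterSet, count_matrix
from codonshift.fit_mcmc import McmcSettings, PosteriorSamples
from codonshift.synthetic_data import (
    LabelSpec,
    SimulationConfig,
    random_parameters,
    simulate_genome,
)


@pytest.fixture(scope="session")
def table():
    return CodonFamilyTable.standard()


@pytest.fixture(scope="session")
def uniform_composition(table):
    fams = [f.family_id for f in table.families]
    return {f: 1.0 / len(fams) for f in fams}


@pytest.fixture(scope="session")
def truth_params(table):
    return random_parameters(table, seed=42)


@pytest.fixture(scope="session")
def small_genome(table, truth_params, uniform_composition):
    """60 genes x ~120 codons under one uniform-composition label."""
    config = SimulationConfig(
        n_genes=60,
        mean_length=120,
        min_length=60,
        sdlog=1.0,
        labels=[LabelSpec("H", uniform_composition, mean_segment_length=10)],
        seed=7,
    )
    return simulate_genome(config, truth_params)


@pytest.fixture(scope="session")
def small_counts(small_genome, table):
    return count_matrix(small_genome.sequences(), table=table)


def make_samples(table, values, n_draws=200, jitter=0.0, seed=0):
    """Fake PosteriorSamples over the 40 free codons.

    ``values`` maps codon -> posterior mean; unnamed free codons default to
    1.0 (so the fitting reference stays the favored codon of its family).
    """
    rng = np.random.default_rng(seed)
    names = []
    cols = []
    for fam in table.families:
        for j, codon in enumerate(fam.codons):
            if j == fam.reference_index:
                continue
            names.append(codon)
            center = values.get(codon, 1.0)
            cols.append(center + jitter * rng.standard_normal(n_draws))
    return PosteriorSamples(
        param_names=names,
        draws=np.column_stack(cols),
        deviance=np.zeros(n_draws),
        seed=seed,
        settings=McmcSettings(n_iterations=10, thin=1),
    )


@pytest.fixture
def fake_samples_factory(table):
    def factory(values, n_draws=200, jitter=0.0, seed=0):
        return make_samples(table, values, n_draws, jitter, seed)

    return factory
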