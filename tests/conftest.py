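import pytest

import cisgrammar as cg


@pytest.fixture(scope="session")
def small_config():
    return cg.SimulationConfig(
        genome_length=400_000, n_peaks_per_class=200, seed=11
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """Genome + planted peak sets shared across scanning/grammar tests."""
    genome = cg.generate_genome(small_config)
    peak_sets, truth = cg.generate_peak_sets(small_config, genome)
    return genome, peak_sets, truth
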