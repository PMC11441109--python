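import pytest

from xksilence import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def default_experiment():
    """The default-condition synthetic experiment (5 cross-kingdom pairs,
    repression 3.0 log2, 3 replicates/condition), with read pools."""
    return simulate_experiment(SimulationConfig(seed=1))


@pytest.fixture()
def tiny_config():
    """A desk-speed configuration for unit tests."""
    return SimulationConfig(
        seed=7,
        n_transcripts_plant=12,
        n_transcripts_fungus=10,
        transcript_len_range=(200, 400),
        n_mirnas_plant=3,
        n_mirnas_fungus=2,
        n_endogenous_pairs=2,
        n_crosskingdom_pairs=2,
        n_de_transcripts=2,
        reads_per_sample=300,
        frac_homologous=0.2,
    )
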