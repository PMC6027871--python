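import pytest

from diagmark.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def clean_sim():
    """The default synthetic study: 7/6/9/8 individuals, 50 clean diagnostic
    + 25 confounder + 400 shared + 40 private sites, no error, no missing."""
    config = SimConfig(seed=11)
    return config, simulate_dataset(config)


@pytest.fixture(scope="session")
def noisy_sim():
    """A smaller dataset with missingness and genotyping error, for I/O and
    robustness checks."""
    config = SimConfig(
        seed=7,
        n_diagnostic_clean=12,
        n_diagnostic_confounded=5,
        n_shared=60,
        n_private_per_group=(3, 3, 3, 3),
        missing_rate=0.06,
        genotyping_error=0.01,
        contig_length=25_000,
    )
    return config, simulate_dataset(config)
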