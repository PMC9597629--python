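"""Shared fixtures: synthetic datasets and pipeline runs (session-scoped)."""

import pytest

from mirrorpg import PipelineConfig, SyntheticConfig, make_demo_dataset, run_pipeline


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """The default synthetic study: 60 genes, 4 mis-annotated starts,
    3 hidden ORFs, 15% fragment dropout, paired 14N/15N spectra."""
    return make_demo_dataset(tmp_path_factory.mktemp("demo"), SyntheticConfig())


@pytest.fixture(scope="session")
def default_report(default_dataset):
    return run_pipeline(PipelineConfig.from_yaml(default_dataset.config_yaml))


@pytest.fixture(scope="session")
def clean_config():
    """A smaller noise-free study (no dropout, no noise peaks)."""
    return SyntheticConfig(
        seed=17,
        genome_length=16_000,
        n_genes=12,
        n_mis_start=2,
        n_hidden_orfs=1,
        fragment_dropout_prob=0.0,
        noise_peaks_per_spectrum=0,
    )


@pytest.fixture(scope="session")
def clean_dataset(tmp_path_factory, clean_config):
    return make_demo_dataset(tmp_path_factory.mktemp("clean"), clean_config)


@pytest.fixture(scope="session")
def clean_report(clean_dataset):
    return run_pipeline(PipelineConfig.from_yaml(clean_dataset.config_yaml))
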