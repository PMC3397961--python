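import pytest

from valvetag import simulate


@pytest.fixture(scope="session")
def small_cfg():
    """A small but fully featured synthetic study used across tests."""
    return simulate.SyntheticConfig(
        n_genes=200, library_depth=200_000, base_tpm=100.0,
        seq_error_rate=0.0, chastity_fail_rate=0.2, gene_spacing=2000,
        n_peaks=20, seed=42,
    )


@pytest.fixture(scope="session")
def small_tx(small_cfg):
    return simulate.simulate_transcriptome(small_cfg)


@pytest.fixture(scope="session")
def small_truth(small_cfg, small_tx):
    return simulate.make_truth(small_cfg, small_tx)


@pytest.fixture(scope="session")
def small_counts(small_cfg, small_truth):
    return simulate.simulate_counts(small_cfg, small_truth)
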