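import numpy as np
import pytest

from triplextad.synthetic import SyntheticConfig, simulate


@pytest.fixture(scope="session")
def small_cfg():
    """A small, fast study system used across test modules."""
    return SyntheticConfig(seed=7, n_chroms=2, chrom_length=150_000, n_tads=8,
                           tad_length_range=(8_000, 14_000), n_lncrnas=30,
                           n_genes=10, tts_enrichment_factor=3.0)


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    return simulate(small_cfg)


@pytest.fixture(scope="session")
def default_bundle():
    """A default-scale study system (1.5 Mb genome, enrichment factor 3)."""
    return simulate(SyntheticConfig(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
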