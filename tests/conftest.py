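import numpy as np
import pytest
from hypothesis import settings

from beanmir.pipeline import run_fixture_analysis, run_synthetic
from beanmir.synthdata import SimConfig, simulate

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def small_config(seed: int = 7) -> SimConfig:
    """A scaled-down study: same structure, fewer genes, fast enough for
    per-test reuse."""
    return SimConfig(n_genes=12, n_novel_genes=3, n_families=6, n_decoys=8,
                     n_shifted_genes=2, n_target_sites=4, n_wobbled_sites=2,
                     n_decoy_ests=4, n_ncrna=8, mean_abundance=200.0,
                     seed=seed)


@pytest.fixture(scope="session")
def small_cfg():
    return small_config()


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """(ReferenceSets, LibrarySet, sizes) for the small seeded study."""
    return simulate(small_cfg)


@pytest.fixture(scope="session")
def small_run(small_cfg):
    """Full pipeline results for the small seeded study."""
    return run_synthetic(small_cfg)


@pytest.fixture(scope="session")
def fixture_run():
    """The bundled printed-table analysis, computed once per session."""
    return run_fixture_analysis()


@pytest.fixture()
def rng():
    return np.random.default_rng(20261001)
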