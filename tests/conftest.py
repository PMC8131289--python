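import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

try:  # quiet RDKit parse warnings during tests
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def small_dataset():
    """A modest mechanistic campaign shared across tests (noise 0.2)."""
    import kpuubrain as kb

    cfg = kb.GeneratorConfig(
        n_compounds=240, seed=17, n_descriptors=16, n_informative=6,
        n_scaffold_families=30, family_spread=0.5, descriptor_noise_sd=0.4,
    )
    return kb.generate_dataset(cfg)


@pytest.fixture(scope="session")
def derived_small(small_dataset):
    from kpuubrain.assays import derive_table

    return derive_table(small_dataset.table)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
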