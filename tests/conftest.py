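import numpy as np
import pytest

from sexqtl.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def default_bundle():
    """One simulated study at the default config (200 genes, 72 eQTL
    blueprints covering all categories x impacts x CRE classes)."""
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced study for stages that do not need the full blueprint
    cross."""
    cfg = SimConfig(seed=7, n_genes=120, n_background_variants=2000,
                    n_background_cres=20, cohort_size=120, n_loci=8)
    return simulate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
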