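import numpy as np
import pytest

from introchron.simulate import SimulationConfig


@pytest.fixture
def small_config():
    """Down-scaled simulation: fast enough for per-test use."""
    return SimulationConfig(
        seed=7,
        n_modern=200,
        n_genes=150,
        n_circadian=25,
        n_variants=2000,
        n_splice_variants=1500,
        n_regulation_genes=30,
        n_eqtl_tuples=4000,
        n_gwas_variants=200,
        n_signif_blocks=8,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
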