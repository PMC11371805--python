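import numpy as np
import pytest

from cosegmap.coseg_classifier import ClassifierParams
from cosegmap.cross_simulator import CrossConfig, simulate_cross
from cosegmap.synthetic_genes import build_pmel_like_gene


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down cross for fast unit tests (one causal + two decoy scaffolds)."""
    return CrossConfig(
        scaffold_lengths=(3_000_000, 2_000_000, 1_500_000),
        causal_pos=1_700_000,
        variant_density=1 / 2000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cross(small_config):
    """(truth, pedigree, panel, founders) for the small cross."""
    return simulate_cross(small_config)


@pytest.fixture(scope="session")
def default_params():
    return ClassifierParams()


@pytest.fixture(scope="session")
def pmel_gene():
    return build_pmel_like_gene()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
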