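import numpy as np
import pytest

from mipam import SyntheticSpectraConfig, generate_block_spectra


@pytest.fixture(scope="session")
def three_block_ds():
    """Small linear block dataset with clean structure (n=60, p=12, 3 blocks)."""
    cfg = SyntheticSpectraConfig(
        n_subjects=60,
        block_sizes=(4, 4, 4),
        noise_sd=0.05,
        affected_blocks=(0,),
        effect_size=1.5,
        seed=11,
    )
    return generate_block_spectra(cfg)


@pytest.fixture(scope="session")
def gaussian_pair():
    """Correlated bivariate normal sample (rho=0.6, n=2000)."""
    rng = np.random.default_rng(21)
    xy = rng.multivariate_normal([0.0, 0.0], [[1.0, 0.6], [0.6, 1.0]], size=2000)
    return xy[:, 0], xy[:, 1]


def random_dissimilarity(rng, p):
    """Random symmetric dissimilarity matrix with null diagonal."""
    a = rng.uniform(0.0, 1.0, size=(p, p))
    d = (a + a.T) / 2
    np.fill_diagonal(d, 0.0)
    return d
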