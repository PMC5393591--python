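import numpy as np
import pytest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170417)


@pytest.fixture(scope="session")
def two_laplace_mixture():
    """Orthogonally mixed pair of Laplace sources with ground truth."""
    from miprest import SourceSpec, make_mixture

    return make_mixture([SourceSpec("laplace")] * 2, n=50_000, seed=42)


@pytest.fixture(scope="session")
def small_overextraction():
    """Rank-5 mixture in 10 channels (2 supergaussian + 3 Gaussian)."""
    from miprest import overextraction_design

    return overextraction_design(n=20_000, seed=7)
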