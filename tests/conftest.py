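import pytest

from critdom import Domain, EnvironmentEnsemble, OffspringPMF, laplace_kernel


@pytest.fixture
def kernel():
    """Laplace kernel with unit mean dispersal distance."""
    return laplace_kernel(1.0)


@pytest.fixture
def pmf():
    """Running-example offspring law: mean 1.5, variance 0.45."""
    return OffspringPMF([0.1, 0.3, 0.6])


@pytest.fixture
def ensemble():
    """Three-environment ensemble with state means 1.6, 1.5, 1.3."""
    return EnvironmentEnsemble.from_pairs(
        [(0.4, [0.1, 0.2, 0.7]), (0.4, [0.1, 0.3, 0.6]), (0.2, [0.2, 0.3, 0.5])]
    )


@pytest.fixture
def domain_critical():
    """Domain at the deterministic critical length of the running example."""
    return Domain(2.703)
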