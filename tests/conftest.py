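import numpy as np
import pytest

from nichecomp.mixing import SourceProfile


@pytest.fixture(scope="session")
def three_sources():
    """Well-separated 3-source triangle with unequal concentrations."""
    return [
        SourceProfile("invertebrates", -25.0, 3.5, 0.50, 0.10),
        SourceProfile("mushrooms", -23.0, 0.5, 0.43, 0.04),
        SourceProfile("earthworms", -27.5, 7.5, 0.40, 0.09),
    ]


@pytest.fixture(scope="session")
def four_sources():
    """Four sources with moderately unequal concentrations (polytope case)."""
    return [
        SourceProfile("a", -25.0, 3.5, 0.50, 0.10),
        SourceProfile("b", -23.0, 0.5, 0.45, 0.06),
        SourceProfile("c", -27.5, 7.5, 0.40, 0.09),
        SourceProfile("d", -24.0, 6.0, 0.48, 0.07),
    ]


@pytest.fixture(scope="session")
def gaussian_cloud():
    rng = np.random.default_rng(42)
    return rng.normal(0.0, 1.0, (2000, 2))
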