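import numpy as np
import pytest

from haplodense import SyntheticSpec, simulate_panel, toy_fixture


@pytest.fixture
def toy():
    return toy_fixture()


@pytest.fixture(scope="session")
def small_panel():
    """100 haplotypes x 150 markers on one chromosome; session-wide reuse."""
    spec = SyntheticSpec(
        n_haplotypes=100,
        chromosomes=(("1", 8000.0, 150),),
        seed=11,
    )
    return simulate_panel(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
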