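import numpy as np
import pytest

from popsel.demography import (
    DemographicModel,
    SelectionGrid,
    build_cache,
    build_equilibrium_cache,
)


@pytest.fixture(scope="session")
def model():
    return DemographicModel.illustrative_default()


@pytest.fixture(scope="session")
def reduced_grid():
    return SelectionGrid.reduced()


@pytest.fixture(scope="session")
def eq_cache(reduced_grid):
    """Cheap single-population equilibrium cache on the reduced grid (n=8),
    folded use is handled inside fit_dfe."""
    return build_equilibrium_cache(reduced_grid, 8)


@pytest.fixture(scope="session")
def demo_cache(model, reduced_grid):
    """2D expected-spectrum cache under the illustrative demography at 8+8
    chromosomes (the study's projected size); built once per session."""
    return build_cache(model, reduced_grid, (8, 8), pts=70)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_spectrum(rng, shape, folded=False):
    from popsel.sfs import Spectrum, fold

    counts = rng.poisson(8.0, size=shape).astype(float)
    spec = Spectrum(counts)
    return fold(spec) if folded else spec
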