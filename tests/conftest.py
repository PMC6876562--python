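import numpy as np
import pytest

from phenocloud.synthetic import intensive_spec, make_orchard


@pytest.fixture(scope="session")
def small_orchard():
    """A modest intensive orchard shared across tests: 10 cone trees,
    heights 1-3 m, reduced ground density to keep the suite quick."""
    spec = intensive_spec(
        n_rows=2,
        n_trees_per_row=5,
        ground_density=1200.0,
        canopy_density=4000.0,
        height_range=(1.0, 3.0),
        seed=7,
    )
    return spec, make_orchard(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
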