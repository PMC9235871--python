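import numpy as np
import pytest

from hypervine.bands import make_band_grid
from hypervine.scene import SceneLayout, render_scene
from hypervine.traits import sample_traits, table2_spec


@pytest.fixture(scope="session")
def grid():
    return make_band_grid()


@pytest.fixture(scope="session")
def spec():
    return table2_spec()


@pytest.fixture(scope="session")
def traits60(spec):
    return sample_traits(spec, 60, 7)


@pytest.fixture(scope="session")
def traits12(spec):
    return sample_traits(spec, 12, 3)


@pytest.fixture(scope="session")
def small_layout():
    # 3 rows x 4 vines at 8 cm GSD keeps rendered cubes small for tests
    return SceneLayout(n_rows=3, vines_per_row=4, gsd=0.08)


@pytest.fixture(scope="session")
def nf_scene(traits12, grid, small_layout):
    """Noise-free small scene: the exact oracle for the imaging chain."""
    return render_scene(traits12, grid, layout=small_layout.noise_free(), seed=3)
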