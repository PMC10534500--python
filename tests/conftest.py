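import numpy as np
import pytest

from dissomap import full_design_table
from dissomap.synth import generate_particle_map, generate_pure_spectra


@pytest.fixture(scope="session")
def designs():
    return full_design_table()


@pytest.fixture(scope="session")
def design_20pct(designs):
    """DR13: 20 w/w% HPMC, <45 µm fraction."""
    d = next(d for d in designs if d.name == "DR13")
    assert d.hpmc_frac == 0.20
    return d


@pytest.fixture(scope="session")
def raman_library():
    return generate_pure_spectra("raman", 320, similarity_target=0.9, seed=1)


@pytest.fixture(scope="session")
def nir_library():
    return generate_pure_spectra("nir", 240, similarity_target=0.9, seed=1)


@pytest.fixture(scope="session")
def particle_map_nir(design_20pct):
    return generate_particle_map(design_20pct, (48, 48), 25.0, seed=3)


@pytest.fixture(scope="session")
def particle_map_raman(design_20pct):
    return generate_particle_map(design_20pct, (31, 31), 40.0, seed=4)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
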