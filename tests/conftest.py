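import numpy as np
import pytest

from petquant.geometry import mmr_reduced, toy_geometry
from petquant.projector import build_transaxial_lut, centred_image
from petquant.synthetic import (SimulationConfig, make_norm_components,
                                make_phantom, simulate_listmode)


@pytest.fixture(scope="session")
def toy4():
    """Small scanner with gaps: 4 rings, 80 positions, 40 angles."""
    return toy_geometry(n_rings=4, n_blocks_tx=16, crystals_per_block=4,
                        gaps_per_block=1)


@pytest.fixture(scope="session")
def toy8():
    """8-ring gapless toy scanner."""
    return toy_geometry(n_rings=8, n_blocks_tx=16, crystals_per_block=4,
                        gaps_per_block=0)


@pytest.fixture(scope="session")
def toy4_grid(toy4):
    return centred_image(toy4, (7, 24, 24), (2.0, 3.0, 3.0))


@pytest.fixture(scope="session")
def toy4_lut(toy4, toy4_grid):
    return build_transaxial_lut(toy4, toy4_grid)


@pytest.fixture(scope="session")
def toy_sim(toy4):
    """Cylinder acquisition on the toy scanner with randoms + scatter."""
    cfg = SimulationConfig(
        phantom={"type": "uniform_cylinder", "diameter_mm": 60.0,
                 "activity": 1.0},
        duration_s=60.0, randoms_fraction=0.2, scatter_fraction=0.1,
        efficiency_cv=0.1, seed=11, target_prompts=3e5)
    emission, mumap, parc = make_phantom(cfg, toy4, shape=(7, 32, 32))
    comps = make_norm_components(toy4, efficiency_cv=0.1, seed=11)
    sim = simulate_listmode(emission, mumap, comps, cfg, toy4)
    return {"cfg": cfg, "emission": emission, "mumap": mumap, "parc": parc,
            "components": comps, "sim": sim, "geom": toy4}
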