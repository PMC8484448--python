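import numpy as np
import pytest

import rodentmap as rm
from rodentmap.impact_mapping import default_scenarios, run_scenarios


def _area_products(cfg):
    hab = rm.simulate_habitats(cfg)
    truth = rm.simulate_impact(hab, cfg)
    scene0, scene1 = rm.render_scene_pair(hab, truth, cfg)
    ndvi0 = rm.compute_ndvi(scene0)
    ndvi1 = rm.compute_ndvi(scene1)
    change = rm.ndvi_change(ndvi0, ndvi1)
    return {
        "cfg": cfg,
        "habitats": hab,
        "truth": truth,
        "scene0": scene0,
        "scene1": scene1,
        "ndvi0": ndvi0,
        "ndvi1": ndvi1,
        "change": change,
    }


@pytest.fixture(scope="session")
def noiseless_area():
    """Nuisance-free scene pair: the truth must be exactly recoverable."""
    cfg = rm.SimConfig(
        grid_size=256,
        seed=5,
        noise_sd=0.0,
        illumination_gain=1.0,
        illumination_offset=0.0,
        coreg_shift=(0.0, 0.0),
    )
    return _area_products(cfg)


@pytest.fixture(scope="session")
def noisy_area():
    """Default study conditions (noise, illumination drift, 2 px shift)."""
    return _area_products(rm.SimConfig(grid_size=256, seed=1))


@pytest.fixture(scope="session")
def noisy_scenarios(noisy_area):
    return run_scenarios(
        noisy_area["change"], noisy_area["habitats"], default_scenarios()
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
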