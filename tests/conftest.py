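import numpy as np
import pytest

from crestmig import synthetic as syn

# small, fast geometry used by most image-level tests
SMALL = dict(image_shape=(1024, 1024), zone_radius=150.0, n_cells_seeded=350)


@pytest.fixture(scope="session")
def small_config():
    return syn.SimulationConfig(**SMALL, arac_mode=True)


@pytest.fixture(scope="session")
def mixed_viability_well(small_config):
    """One well with 10% planted non-viable cells, plus its rendered channels."""
    drug = syn.DrugEffectModel(ec_mig=105.0, death_fraction=0.1)
    gtw = syn.simulate_well(small_config, drug, 50.0, seed=42)
    nuc, cal = syn.render_well(
        gtw, small_config.image_shape, syn.RenderParams(seed=43)
    )
    return gtw, nuc, cal


@pytest.fixture(scope="session")
def blank_image():
    rng = np.random.default_rng(0)
    img = 100.0 + rng.normal(0, 5, size=(256, 256))
    return np.clip(img, 0, 65535).astype(np.uint16)
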