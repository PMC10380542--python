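import numpy as np
import pytest

from seedcascade import (
    GM,
    NON_GM,
    ModelSpec,
    SimDesign,
    TrainConfig,
    make_band_axis,
    simulate_spectrum_set,
    train_model,
)


@pytest.fixture(scope="session")
def separable_design():
    """Two well-separated 'varieties', no GM structure, tiny and noiseless-ish."""
    axis = make_band_axis("thz", 24, 0.3, 2.0)
    templates = np.stack([np.full(24, 0.3), np.full(24, 0.9)])
    sizes = {("a", NON_GM): 30, ("b", NON_GM): 30}
    return SimDesign(axis, ("a", "b"), templates, np.zeros(24), [], 0.01, sizes, rng_seed=5)


@pytest.fixture(scope="session")
def separable_set(separable_design):
    return simulate_spectrum_set(separable_design)


@pytest.fixture(scope="session")
def tiny_trained_model(separable_set):
    """A small model trained to separate the two flat templates."""
    model, hist = train_model(
        separable_set,
        separable_set.variety_labels,
        TrainConfig(epochs=50, learning_rate=1e-3, batch_size=16, rng_seed=5),
        ModelSpec.scaled(24, 2, scale=16),
    )
    return model, hist


@pytest.fixture(scope="session")
def planted_binary():
    """Binary set whose classes differ only at planted bands (clear offset)."""
    planted = np.array([4, 11, 18])
    axis = make_band_axis("nir", 24, 900.0, 1700.0)
    templates = np.full((1, 24), 0.5)
    offset = np.zeros(24)
    offset[planted] = -0.2
    sizes = {("v", GM): 40, ("v", NON_GM): 40}
    design = SimDesign(axis, ("v",), templates, offset, planted, 0.02, sizes, rng_seed=9)
    return simulate_spectrum_set(design), planted
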