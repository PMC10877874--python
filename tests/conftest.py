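import numpy as np
import pytest

import ovadx as ox


@pytest.fixture(scope="session")
def small_dataset():
    """30 mixed-shape 64x64 phantoms, moderate contrast."""
    spec = ox.PhantomSpec(image_size=64, tumor_intensity_contrast=0.5,
                          noise_sd=0.05, seed=42)
    return ox.generate_phantom_dataset(spec, 30)


@pytest.fixture(scope="session")
def strong_cohort():
    """Default-size cohort (185 cases / 138+339+92 controls), strong signal."""
    return ox.generate_cohort(ox.CohortSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_net():
    """A small float64 network for exact-arithmetic structural tests."""
    cfg = ox.NetworkConfig.reduced_default(
        input_size=32, reduction_channels=4, head_channels=(4, 1),
        reduced_channels=(4, 6, 8), seed=3,
    )
    net = ox.build_network(cfg)
    for layer, name in net.param_slots():
        layer.params[name] = layer.params[name].astype(np.float64)
    return net
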