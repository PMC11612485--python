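import numpy as np
import pytest

from mitoquant import SceneSpec, render_scene


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free, network-free scene with sparse puncta: under these
    conditions every punctum is separated and unoccluded, so detection is
    exact and the scene serves as a deterministic oracle."""
    return SceneSpec(
        field_shape=(512, 512),
        red_only_density=0.0065,
        double_positive_density=0.002,
        network_density=0.0,
        shot_noise=False,
        read_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def clean_scene(clean_spec):
    # this seed realizes 20 red-only puncta, all pairwise separated by
    # > 2 µm and clear of the double-positive puncta (the preconditions
    # under which detection is exact)
    return render_scene(clean_spec, seed=6)


@pytest.fixture(scope="session")
def default_scene():
    spec = SceneSpec(
        field_shape=(256, 256),
        red_only_density=0.01,
        double_positive_density=0.003,
    )
    return spec, render_scene(spec, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
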