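import numpy as np
import pytest

from bonecsg.phantom import make_phantom_volume, scaled_phantom_spec


@pytest.fixture(scope="session")
def small_phantom():
    """A modest untilted bone phantom shared by volume-pipeline tests."""
    spec = scaled_phantom_spec(24.0, voxel_size_mm=0.15, noise_sd=5.0, seed=11)
    volume, truths = make_phantom_volume(spec)
    return spec, volume, truths


@pytest.fixture(scope="session")
def tilted_phantom_pair():
    """The same phantom generated untilted and tilted (20, 10, 5) degrees."""
    base = dict(voxel_size_mm=0.15, noise_sd=5.0, seed=12)
    flat, _ = make_phantom_volume(scaled_phantom_spec(24.0, **base))
    tilted, _ = make_phantom_volume(
        scaled_phantom_spec(24.0, tilt_euler_deg=(20.0, 10.0, 5.0), **base)
    )
    return flat, tilted


def rel_err(measured, truth):
    return abs(measured - truth) / abs(truth)
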