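import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "tofsig",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("tofsig")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def random_volume(rng):
    """Small random volume with anisotropic spacing."""
    from tofsig import Volume

    return Volume(data=rng.normal(size=(6, 7, 5)), spacing=(0.8, 1.1, 0.6))


@pytest.fixture
def gaussian_tube():
    """Noise-free Gaussian tube phantom with its analytic oracle.

    sigma = 4 mm sampled at sigma/4 spacing; the tube axis is the volume's
    z axis, so iso surfaces are cylinders of known radius.
    """
    from tofsig import PhantomSpec, generate_phantom

    spec = PhantomSpec(
        geometry="straight_tube",
        radius=4.0,
        profile="gaussian",
        sigma=4.0,
        amplitude=100.0,
        background=5.0,
        noise_sd=0.0,
        spacing=(1.0, 1.0, 1.0),
        shape=(20, 20, 14),
    )
    vol, oracle = generate_phantom(spec)
    return spec, vol, oracle


@pytest.fixture
def sigmoid_tube():
    """Noise-free plug-flow (plateau + sigmoid wall falloff) tube phantom."""
    from tofsig import PhantomSpec, generate_phantom

    spec = PhantomSpec(noise_sd=0.0)
    vol, oracle = generate_phantom(spec)
    return spec, vol, oracle
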