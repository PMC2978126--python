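import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from spectravasc import (
    PhantomSpec,
    generate_vessel_network,
    make_ground_truth,
    render_library,
)


@pytest.fixture(scope="session")
def small_phantom():
    """One seeded noise-free phantom (small field, ~8% vessel fraction)."""
    spec = PhantomSpec(
        width_px=192, height_px=192, vessel_area_target=0.08, seed=11, noise_sd=0.0
    )
    net = generate_vessel_network(spec)
    truth = make_ground_truth(net, spec)
    lib = render_library(truth, noise_sd=0.0)
    return spec, net, truth, lib


@pytest.fixture(scope="session")
def noisy_phantom(small_phantom):
    spec, net, truth, _ = small_phantom
    lib = render_library(truth, noise_sd=0.02, seed=99)
    return spec, net, truth, lib
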