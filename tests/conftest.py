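import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bmorim.phantom import PhantomSpec, generate_phantom

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def small_random_phantom(seed: int, n_spokes: int | None = None, noise: bool = True):
    """A randomized, modestly sized synthetic scan for property tests."""
    rng = np.random.default_rng(seed)
    n = n_spokes or int(rng.integers(8, 21))
    spec = PhantomSpec(
        n_spokes=n,
        bmo_semi_axes=(float(rng.uniform(0.6, 1.0)), float(rng.uniform(0.5, 0.9))),
        bmo_tilt_deg=float(rng.uniform(-5, 5)),
        rim_height=float(rng.uniform(0.4, 1.2)),
        cup_depth=float(rng.uniform(0.0, 0.4)),
        rim_slope_width=float(rng.uniform(0.1, 0.3)),
        axial_noise_sd=float(rng.uniform(0.0, 0.02)) if noise else 0.0,
        radial_samples=int(rng.integers(8, 16)),
        r_max=1.5,
        seed=int(rng.integers(2**31)),
        eye="OD" if rng.random() < 0.5 else "OS",
    )
    return generate_phantom(spec).scan


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
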