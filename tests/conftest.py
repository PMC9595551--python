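import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """A quick-to-generate phantom: ~21 lacunae + 1 canal in a 60^3 domain."""
    from lacuna3d import PhantomParams

    return PhantomParams(
        shape=(60, 60, 60),
        spacing=(1.0, 1.0, 1.0),
        concentration_per_mm3=95_000.0,
        n_canals=1,
        seed=42,
    )


@pytest.fixture(scope="session")
def clean_small_phantom():
    """Session-shared clean phantom (grid, mask, truth)."""
    from lacuna3d import PhantomParams, make_phantom

    params = PhantomParams(
        shape=(80, 80, 80),
        spacing=(1.0, 1.0, 1.0),
        concentration_per_mm3=95_000.0,
        n_canals=2,
        seed=7,
    )
    return params, make_phantom(params)
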