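import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def small_case(seed=0, motion=(10.0, 10.0), n_views=2, span=30.0, **kwargs):
    """32-cube, 2 mm spacing two-bone case: same physical extent as the
    64-cube phantom at a quarter of the cost."""
    from polypose.phantom import PhantomConfig, generate_case

    cfg_keys = {k: kwargs.pop(k) for k in ("bones",) if k in kwargs}
    cfg = PhantomConfig(grid_shape=(32, 32, 32), spacing_mm=(2.0, 2.0, 2.0), seed=seed, **cfg_keys)
    kwargs.setdefault("detector_shape", (32, 32))
    kwargs.setdefault("pixel_spacing", (5.0, 5.0))
    return generate_case(cfg, motion[0], motion[1], n_views, span, **kwargs)
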