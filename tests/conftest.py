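import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=200,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20230925)


def random_stack(rng, *, signed, max_depth, nframes, npix_range=(1, 200)):
    """Random frame stack whose values span bit depths up to max_depth."""
    npix = int(rng.integers(*npix_range, endpoint=True))
    h, w = 1, npix  # flat frames keep shapes arbitrary w.r.t. block size
    if signed:
        d = max(int(max_depth), 1)
        lo, hi = -(1 << (d - 1)), (1 << (d - 1)) - 1
        vals = rng.integers(lo, hi, size=(nframes, h, w), dtype=np.int64,
                            endpoint=True)
    else:
        hi = (1 << int(max_depth)) - 1
        vals = rng.integers(0, hi, size=(nframes, h, w), dtype=np.uint64,
                            endpoint=True)
    return vals
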