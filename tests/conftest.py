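import numpy as np
import pytest

from achrf import PhantomSpec, count_scan, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """A default-geometry phantom with 20 implanted foci."""
    spec = PhantomSpec(focus_count=20, seed=42)
    scan, truth = generate_phantom(spec)
    return spec, scan, truth


@pytest.fixture(scope="session")
def counted_phantom(default_phantom):
    """The default phantom plus the full pipeline's result and segmentation."""
    spec, scan, truth = default_phantom
    result, seg = count_scan(scan)
    return spec, scan, truth, result, seg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
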