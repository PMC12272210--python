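import numpy as np
import pytest

from rootlet_levels import (
    LabelVolume,
    PhantomSpec,
    generate_phantom,
)


@pytest.fixture(scope="session")
def default_phantom():
    """Default 0.8 mm straight phantom with C2-C8 levels."""
    spec = PhantomSpec()
    cord, rootlets, truth = generate_phantom(spec)
    return spec, cord, rootlets, truth


@pytest.fixture(scope="session")
def sine_phantom():
    """Lordotic (sagittal-sine) phantom, otherwise identical defaults."""
    spec = PhantomSpec(centerline_kind="sagittal_sine")
    cord, rootlets, truth = generate_phantom(spec)
    return spec, cord, rootlets, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_volume(data, spacing=(1.0, 1.0, 1.0)) -> LabelVolume:
    """Small LPI-oriented volume for unit tests."""
    aff = np.diag([-spacing[0], -spacing[1], -spacing[2], 1.0])
    return LabelVolume(np.asarray(data), aff)
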