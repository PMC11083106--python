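import numpy as np
import pytest

from skindwi.adc import BValuePair
from skindwi.io import DWIStudy, VOIMask
from skindwi.phantom import PhantomSpec, make_skin_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def pair():
    return BValuePair(50.0, 800.0)


@pytest.fixture
def clean_spec():
    """Noise-free default phantom spec."""
    return PhantomSpec(noise_sigma=0.0, seed=7)


@pytest.fixture
def clean_phantom(clean_spec):
    return make_skin_phantom(clean_spec)


def make_uniform_study(
    s_low: float,
    s_high: float,
    shape=(4, 4, 3),
    b_values=(50.0, 800.0),
    case_id="uniform",
    group=None,
) -> DWIStudy:
    """Study with spatially-constant signal at each b-value."""
    vols = np.stack(
        [np.full(shape, s) for s in (s_low, s_high)], axis=-1
    )
    return DWIStudy(
        volumes=vols, b_values=b_values, case_id=case_id, group=group
    )


def full_mask(shape=(4, 4, 3)) -> VOIMask:
    return VOIMask(data=np.ones(shape, dtype=bool))
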