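import numpy as np
import pytest

from lumicat import phantom, preprocess


@pytest.fixture
def healthy_spec():
    return phantom.PhantomSpec(condition="healthy", seed=7)


@pytest.fixture
def healthy_phantom(healthy_spec):
    return phantom.generate_eye_image(healthy_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def masked_lens(healthy_phantom):
    image, truth = healthy_phantom
    return preprocess.mask_image(image, truth.lens_mask)
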