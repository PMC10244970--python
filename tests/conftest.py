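import numpy as np
import pytest

from chronopop.channels import DurationChannelModel


@pytest.fixture(scope="session")
def fitted_model():
    """Default duration-channel model, calibrated once per session."""
    return DurationChannelModel().fit()


@pytest.fixture(scope="session")
def fitted_lowpass_model():
    """Low-pass front-end variant of the default model."""
    return DurationChannelModel(filter_family="lowpass").fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
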