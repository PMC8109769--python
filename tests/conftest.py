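import numpy as np
import pytest

import sganfield as sf


@pytest.fixture(scope="session")
def field_params():
    return sf.FieldParams(seed=42)


@pytest.fixture(scope="session")
def tiny_dataset(field_params):
    """60 synthetic images (30 per class) at 64x64, raw uint8."""
    return sf.generate_dataset(30, field_params)


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest trainable setup: 32x32 images, narrow nets."""
    return sf.GanConfig.desk_profile(base=2, gen_width=16, disc_width=4, epochs=2, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
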