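import numpy as np
import pytest

from aisqa import SyntheticConfig, default_prototypes, synthesize_recording


@pytest.fixture(scope="session")
def prototypes():
    """Ideal prototype set fitted to generated excellent recordings."""
    return default_prototypes(seed=0)


@pytest.fixture(scope="session")
def clean_recording():
    """One clean normal-sinus recording with its ground truth."""
    cfg = SyntheticConfig(seed=101, snr_db=30.0, mean_hr=72.0)
    return synthesize_recording(cfg)


@pytest.fixture(scope="session")
def clean_af_recording():
    cfg = SyntheticConfig(seed=202, rhythm="AF", snr_db=30.0, mean_hr=80.0)
    return synthesize_recording(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
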