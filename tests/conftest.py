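import numpy as np
import pytest

from pflsteer.model import ModelParams, NetworkCalibration


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def default_calib(default_params) -> NetworkCalibration:
    """One network calibration shared across the suite (ensemble covers the
    S values the tests sweep)."""
    return NetworkCalibration.from_params(
        default_params, s_ensemble=[0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
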