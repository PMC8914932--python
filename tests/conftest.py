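import numpy as np
import pytest

from spf import (CalibrationPolynomial, GaitProfileParams, ImuThresholds,
                 SensingThresholds, TactelLayout, simulate_trial)


@pytest.fixture(scope="session")
def poly():
    return CalibrationPolynomial()


@pytest.fixture(scope="session")
def layout():
    return TactelLayout.default()


@pytest.fixture(scope="session")
def thresholds():
    return SensingThresholds()


@pytest.fixture(scope="session")
def imu_thr():
    return ImuThresholds()


@pytest.fixture(scope="session")
def quiet_trial():
    """Small noise-free trial: 3 strides, deterministic."""
    params = GaitProfileParams(n_strides=3, seed=7, noise_sd_voltage=0.0,
                               noise_sd_accel=0.0, noise_sd_gyro=0.0,
                               noise_sd_force=0.0)
    return simulate_trial(params)


@pytest.fixture(scope="session")
def noisy_trial():
    """Small trial at the default noise levels."""
    return simulate_trial(GaitProfileParams(n_strides=5, seed=11))
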