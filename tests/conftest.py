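import numpy as np
import pytest

from armfusion.simulate import TrialConfig, simulate_trial


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def clean_trial():
    """Noise-free, bias-free proper trial: the tracker's ideal conditions."""
    cfg = TrialConfig.proper(
        duration=60.0,
        gyro_bias_deg_s=0.0,
        gyro_noise_sd_deg_s=0.0,
        acc_noise_sd=0.0,
        robot_pos_noise_sd=0.0,
        seed=11,
    )
    return simulate_trial(cfg)


@pytest.fixture(scope="session")
def noisy_comp_trial():
    """Compensatory trial under the default noise and 0.34 deg/s bias."""
    cfg = TrialConfig.compensatory(duration=110.0, seed=13)
    return simulate_trial(cfg)


def random_unit_quat(rng, n=None):
    q = rng.standard_normal((n, 4) if n else 4)
    return q / np.linalg.norm(q, axis=-1, keepdims=True)
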