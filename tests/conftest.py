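import pytest

from embryomir.simulate import SimConfig, simulate_experiment


@pytest.fixture()
def noise_free_dataset():
    """Three-stage + UC experiment with zero measurement noise."""
    cfg = SimConfig(seed=11, ct_noise_sd=0.0, include_uc=True)
    return simulate_experiment(cfg)


@pytest.fixture()
def noisy_dataset():
    """Three-stage experiment at the default noise level."""
    return simulate_experiment(SimConfig(seed=11))
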