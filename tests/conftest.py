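import numpy as np
import pytest

from wavepac import SynthParams, simulate_asymmetric_oscillation

FS = 512.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def asymmetric_signal():
    """10 s noiseless shaped oscillation with both kinds of asymmetry."""
    params = SynthParams(duration=10, fs=FS, osc_freq=20, rdsym=0.6,
                         peak_exp=2.0, noise_amp=0.0, gamma_amp=0.0)
    return simulate_asymmetric_oscillation(params)


@pytest.fixture(scope="session")
def noisy_asymmetric_signal():
    """10 s shaped oscillation plus a mild 1/f background."""
    from wavepac import simulate_aperiodic

    params = SynthParams(duration=10, fs=FS, osc_freq=20, rdsym=0.6,
                         peak_exp=2.0, noise_amp=0.0, gamma_amp=0.0, seed=7)
    x = simulate_asymmetric_oscillation(params)
    return x + 0.3 * simulate_aperiodic(2.0, x.size, FS, seed=7)


@pytest.fixture(scope="session")
def symmetric_sine():
    """60 s noiseless 20 Hz sinusoid."""
    t = np.arange(int(60 * FS)) / FS
    return np.sin(2 * np.pi * 20 * t)
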