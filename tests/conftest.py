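import numpy as np
import pytest

from rhythmnet import (EpochedSignal, SignalConfig, SpikeCouplingConfig,
                       TaskConfig, BehaviorConfig, generate_trials,
                       simulate_session, synthesize_lfp)


@pytest.fixture(scope="session")
def small_trials():
    return generate_trials(TaskConfig(n_trials=80, seed=11))


@pytest.fixture(scope="session")
def small_lfp(small_trials):
    return synthesize_lfp(small_trials, SignalConfig(seed=3))


@pytest.fixture(scope="session")
def small_session():
    sess, truth = simulate_session(
        task=TaskConfig(n_trials=100, seed=7),
        signal=SignalConfig(seed=8),
        behavior=BehaviorConfig(seed=9),
        spikes={"u1": ("mdPul", SpikeCouplingConfig(kappa=1.5, seed=10))},
        rois=("mdPul", "FEF"), seed=7)
    return sess


def cosine_epochs(freq_hz, n_trials=3, epoch_ms=(-1000.0, 500.0),
                  rate_hz=1000.0, amplitude=1.0, phase0=0.0,
                  roi="A", channel="c"):
    t0, t1 = epoch_ms
    n = int(round((t1 - t0) * rate_hz / 1000.0))
    t = (t0 + np.arange(n) * 1000.0 / rate_hz) / 1000.0
    x = amplitude * np.cos(2 * np.pi * freq_hz * t + phase0)
    return EpochedSignal(roi, channel, "target", t0, rate_hz,
                         np.tile(x, (n_trials, 1)), np.arange(n_trials))
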