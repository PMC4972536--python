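import numpy as np
import pytest

from vesiclekin import synthgen as sg


@pytest.fixture(scope="session")
def snr10_recording():
    """200 simulated fusion events (amplitude 20 pA on 2 pA baseline noise,
    SNR 10) on a 120 s trace at 25 kHz, with a minimum 40 ms separation."""
    rng = np.random.default_rng(42)
    n_ev, duration = 200, 120.0
    onsets = np.sort(rng.uniform(100.0, duration * 1e3 - 200.0, n_ev))
    for i in range(1, n_ev):
        onsets[i] = max(onsets[i], onsets[i - 1] + 40.0)
    schedule = [
        sg.EventTruth(onset_time=float(t), foot_duration=3.0,
                      foot_amplitude=6.0, spike_amplitude=20.0,
                      rise_tau=0.1, decay_tau=2.0)
        for t in onsets
    ]
    trace, truth = sg.gen_amperometric_trace(
        schedule, duration=duration, fs=25_000.0, baseline_sd=2.0, seed=1)
    return trace, truth, onsets


@pytest.fixture(scope="session")
def cap_truth():
    return sg.CapTruth(A0=5000.0, A1=50.0, tau1=0.02, A2=80.0, tau2=0.25,
                       k=20.0, delay=3.0, flash_time=0.1, noise_sd=0.0)
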