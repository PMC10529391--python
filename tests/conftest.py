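import numpy as np
import pytest

from pahydro import PASignal, SecondOrderParams, simulate_pa_signal


@pytest.fixture
def reference_params() -> SecondOrderParams:
    """A mid-panel underdamped oscillator (1.59 MHz, zeta 0.25)."""
    return SecondOrderParams(omega_n=1e7, zeta=0.25, gain=1e-9)


@pytest.fixture
def clean_signal(reference_params) -> PASignal:
    """Noise-free impulse response, 2000 samples at 10 ns."""
    return simulate_pa_signal(reference_params, ts=1e-8, n_samples=2000)


@pytest.fixture
def noisy_signal(reference_params) -> PASignal:
    """Same trace at 20 dB SNR with a fixed noise seed."""
    return simulate_pa_signal(
        reference_params, ts=1e-8, n_samples=2000, noise_snr_db=20.0, seed=123
    )
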