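import numpy as np
import pytest

from pahydro import (
    NoArrivalError,
    PASignal,
    SampleGeometry,
    SecondOrderParams,
    arrival_time,
    compute_features,
    peak_to_peak,
    simulate_pa_signal,
    speed_of_sound,
)
from pahydro.features import write_feature_table

# measured panel: (MW, PVA %, D mm, ta us, c m/s) - printed reference values
MEASURED_PANEL = [
    ("MW1", 7, 39.70, 25.60, 1551),
    ("MW1", 9, 43.16, 28.18, 1532),
    ("MW1", 12, 45.00, 28.45, 1582),
    ("MW1", 15, 46.22, 30.14, 1534),
    ("MW1", 20, 46.62, 30.82, 1513),
    ("MW2", 7, 40.20, 26.39, 1523),
    ("MW2", 9, 40.54, 27.08, 1497),
    ("MW2", 12, 43.84, 28.63, 1531),
    ("MW2", 15, 43.89, 28.67, 1531),
]


class TestPeakToPeak:
    def test_sinusoid_gives_twice_amplitude(self):
        t = np.arange(1000) * 1e-8
        sig = PASignal(3.0 * np.sin(2 * np.pi * 1e6 * t), ts=1e-8)
        assert peak_to_peak(sig, window=(0.0, t[-1])) == pytest.approx(6.0, rel=1e-3)

    def test_constant_signal_is_zero(self):
        sig = PASignal(np.full(100, 2.5), ts=1e-8)
        assert peak_to_peak(sig) == 0.0

    def test_matches_closed_form_trace(self):
        p = SecondOrderParams(omega_n=1e7, zeta=0.3, gain=2e-9)
        sig = simulate_pa_signal(p, ts=1e-9, n_samples=5000)
        expected = sig.samples.max() - sig.samples.min()
        assert peak_to_peak(sig, window=(0, sig.times[-1])) == expected

    def test_empty_window_rejected(self):
        sig = PASignal(np.arange(10.0), ts=1.0)
        with pytest.raises(ValueError, match="window"):
            peak_to_peak(sig, window=(100.0, 200.0))


class TestArrivalTime:
    def test_known_delay_detected_within_one_sample(self):
        p = SecondOrderParams(omega_n=2 * np.pi * 2.25e6, zeta=0.2, gain=1e-9)
        sig = simulate_pa_signal(p, ts=4e-9, n_samples=10000, delay=25.60e-6)
        ta = arrival_time(sig)
        # threshold crossing happens within the first quarter-period
        assert ta >= 25.60e-6
        assert ta - 25.60e-6 < 0.25 / 2.25e6

    def test_zero_signal_has_no_arrival(self):
        with pytest.raises(NoArrivalError):
            arrival_time(PASignal(np.zeros(100), ts=1.0))

    def test_noise_robustness_median_error_below_two_samples(self):
        p = SecondOrderParams(omega_n=2 * np.pi * 2.25e6, zeta=0.2, gain=1e-9)
        clean = simulate_pa_signal(p, ts=4e-9, n_samples=10000, delay=25.60e-6)
        ta_clean = arrival_time(clean)
        errors = []
        for seed in range(50):
            noisy = simulate_pa_signal(
                p, ts=4e-9, n_samples=10000, delay=25.60e-6, noise_snr_db=20, seed=seed
            )
            errors.append(abs(arrival_time(noisy) - ta_clean) / 4e-9)
        assert np.median(errors) < 2.0

    def test_first_peak_method_lands_on_extremum(self):
        p = SecondOrderParams(omega_n=1e7, zeta=0.2, gain=1e-9)
        sig = simulate_pa_signal(p, ts=1e-9, n_samples=5000, delay=1e-6)
        ta = arrival_time(sig, method="first-peak")
        k = int(round((ta - sig.t0) / sig.ts))
        assert abs(sig.samples[k]) >= abs(sig.samples[k - 1])
        assert abs(sig.samples[k]) >= abs(sig.samples[k + 1])

    def test_equivariant_under_time_shift(self):
        p = SecondOrderParams(omega_n=1e7, zeta=0.2, gain=1e-9)
        sig = simulate_pa_signal(p, ts=1e-8, n_samples=2000, delay=5e-6)
        shifted = sig.shifted(3e-6)
        assert arrival_time(shifted) == pytest.approx(arrival_time(sig) + 3e-6, abs=1e-12)


class TestSpeedOfSound:
    def test_unit_conversion_anchor(self):
        assert speed_of_sound(1.0, 1.0) == pytest.approx(1000.0)

    @pytest.mark.parametrize("mw,conc,D,ta,c", MEASURED_PANEL)
    def test_reproduces_measured_panel_speeds(self, mw, conc, D, ta, c):
        assert round(speed_of_sound(D, ta)) == c

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            speed_of_sound(0.0, 1.0)
        with pytest.raises(ValueError):
            speed_of_sound(1.0, -1.0)


class TestFeatureTable:
    def test_compute_and_write(self, tmp_path):
        p = SecondOrderParams(omega_n=2 * np.pi * 2.25e6, zeta=0.2, gain=1e-9)
        sig = simulate_pa_signal(p, ts=4e-9, n_samples=10000, delay=25.60e-6)
        feats = compute_features(sig, SampleGeometry(D=39.70))
        assert feats.c == pytest.approx(1551, abs=3)
        out = tmp_path / "features.csv"
        df = write_feature_table(
            [{
                "sample_id": "MW1-7pct", "MW": "MW1", "concentration": 7,
                "D_mm": 39.70, "ta_us": feats.t_a, "c_m_s": feats.c,
                "amplitude_mV": feats.amplitude_pp,
            }],
            out,
        )
        assert out.exists()
        assert list(df.columns) == [
            "sample_id", "MW", "concentration", "D_mm", "ta_us", "c_m_s", "amplitude_mV",
        ]

    def test_geometry_requires_positive_diameter(self):
        with pytest.raises(ValueError):
            SampleGeometry(D=-1.0)
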