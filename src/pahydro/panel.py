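"""Synthetic nine-hydrogel panel generator.

The study system is a panel of nine box-shaped PVA hydrogels: five
concentrations (7, 9, 12, 15, 20%) at the lower molecular weight (MW1)
and four (7, 9, 12, 15%) at the higher one (MW2).  Each measured PA trace
is emulated as a delayed, noisy second-order impulse response whose
parameters follow the concentration trends observed on such phantoms:

* damping ratio rises linearly with concentration (more PVA absorbs more
  acoustic energy), spanning roughly 0.1-0.5;
* natural frequency falls quadratically with concentration, spanning
  roughly 3 down to 1.2 MHz around the 2.25 MHz transducer band;
* peak-to-peak amplitude rises and the acoustic arrival time lengthens
  with concentration; the per-sample diameters, arrival times and
  amplitudes are anchored to the measured values of the physical panel.

Records default to 40 us at a 1 ns sampling interval (1 GS/s — a
tractable stand-in for the instrument's 10 GS/s rate; the dominant
oscillation is still oversampled by two to three orders of magnitude).
Each recorded trace is the average of three repeated shots, matching the
measurement protocol, with additive white Gaussian noise at 20 dB SNR per
shot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import PASignal, SampleMeta, SecondOrderParams, simulate_pa_signal

__all__ = [
    "PanelSample",
    "PanelSpec",
    "generate_panel",
    "linear_zeta_trend",
    "quadratic_frequency_trend",
]

CONCENTRATIONS = {"MW1": (7.0, 9.0, 12.0, 15.0, 20.0), "MW2": (7.0, 9.0, 12.0, 15.0)}

# measured panel anchors per (MW, concentration %):
# outer diameter D (mm), arrival time (us), peak-to-peak amplitude (mV)
PANEL_ANCHORS = {
    ("MW1", 7.0): (39.70, 25.60, 0.87),
    ("MW1", 9.0): (43.16, 28.18, 1.51),
    ("MW1", 12.0): (45.00, 28.45, 1.70),
    ("MW1", 15.0): (46.22, 30.14, 4.07),
    ("MW1", 20.0): (46.62, 30.82, 6.66),
    ("MW2", 7.0): (40.20, 26.39, 1.50),
    ("MW2", 9.0): (40.54, 27.08, 1.59),
    ("MW2", 12.0): (43.84, 28.63, 3.41),
    ("MW2", 15.0): (43.89, 28.67, 4.06),
}


def linear_zeta_trend(concentration: float, mw: str = "MW1") -> float:
    """Target damping ratio: linear in concentration, 0.1 at 7% up to 0.5
    at 20% for MW1; MW2 sits 0.04 higher (higher MW damps more)."""
    base = 0.1 + (0.4 / 13.0) * (concentration - 7.0)
    return base + (0.04 if mw == "MW2" else 0.0)


def quadratic_frequency_trend(concentration: float, mw: str = "MW1") -> float:
    """Target natural frequency in rad/s: quadratic decrease with
    concentration, 3 MHz at 7% down to 1.2 MHz at 20% for MW1; MW2 is
    0.2 MHz lower (denser gels transfer energy at lower resonance)."""
    f_mhz = 3.0 - 1.8 * (concentration**2 - 49.0) / 351.0
    if mw == "MW2":
        f_mhz -= 0.2
    return 2.0 * np.pi * f_mhz * 1e6


@dataclass(frozen=True)
class PanelSample:
    """Ground-truth parameters of one synthetic panel member."""

    mw: str
    concentration: float
    zeta: float
    omega_n: float  # rad/s
    gain: float  # V*s
    delay: float  # s
    D: float  # mm
    snr_db: Optional[float] = 20.0

    @property
    def sample_id(self) -> str:
        return f"{self.mw}-{self.concentration:g}pct"


def _unit_gain_peak_to_peak(omega_n: float, zeta: float) -> float:
    """Peak-to-peak of the unit-gain impulse response, on a dense grid."""
    sigma = zeta * omega_n
    t_end = 6.0 / sigma if sigma > 0 else 2.0 * 2.0 * np.pi / omega_n
    t = np.linspace(0.0, t_end, 4000)
    wd = omega_n * np.sqrt(1.0 - zeta**2)
    y = (omega_n / np.sqrt(1.0 - zeta**2)) * np.exp(-sigma * t) * np.sin(wd * t)
    return float(y.max() - y.min())


@dataclass
class PanelSpec:
    """Specification of the synthetic panel.

    The default emulates the nine-hydrogel study: per-sample damping
    ratio from :func:`linear_zeta_trend`, natural frequency from
    :func:`quadratic_frequency_trend`, and diameters, delays and
    amplitudes taken from the measured panel anchors.
    """

    samples: List[PanelSample]
    ts: float = 1e-9
    duration: float = 40e-6
    n_shots: int = 3  # each recorded trace is the average of three shots

    @classmethod
    def default(
        cls,
        mws: Tuple[str, ...] = ("MW1", "MW2"),
        snr_db: Optional[float] = 20.0,
        ts: float = 1e-9,
        duration: float = 40e-6,
        n_shots: int = 3,
    ) -> "PanelSpec":
        samples = []
        for mw in mws:
            for conc in CONCENTRATIONS[mw]:
                if not 0 < conc <= 25:
                    raise ValueError(f"unexpected concentration {conc}")
                D, ta_us, amp_mv = PANEL_ANCHORS[(mw, conc)]
                zeta = linear_zeta_trend(conc, mw)
                omega_n = quadratic_frequency_trend(conc, mw)
                gain = (amp_mv * 1e-3) / _unit_gain_peak_to_peak(omega_n, zeta)
                samples.append(
                    PanelSample(
                        mw=mw, concentration=conc, zeta=zeta, omega_n=omega_n,
                        gain=gain, delay=ta_us * 1e-6, D=D, snr_db=snr_db,
                    )
                )
        return cls(samples=samples, ts=ts, duration=duration, n_shots=n_shots)


def generate_panel(
    spec: Optional[PanelSpec] = None,
    seed: int = 0,
) -> Tuple[List[PASignal], pd.DataFrame]:
    """Simulate one PA trace per panel member plus a ground-truth table.

    Per-sample noise seeds are drawn deterministically from ``seed``, so
    the same seed reproduces the panel exactly.  Returns the list of
    signals and a DataFrame with the generating parameters (damping
    ratio, natural frequency, gain, delay, diameter, SNR, noise seed).
    """
    spec = spec or PanelSpec.default()
    n_samples = int(round(spec.duration / spec.ts))
    n_shots = max(1, spec.n_shots)
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=(len(spec.samples), n_shots))
    signals: List[PASignal] = []
    rows = []
    for sample, shot_seeds in zip(spec.samples, child_seeds):
        params = SecondOrderParams(omega_n=sample.omega_n, zeta=sample.zeta, gain=sample.gain)
        meta = SampleMeta(
            mw=sample.mw,
            concentration=sample.concentration,
            diameter_mm=sample.D,
            sample_id=sample.sample_id,
        )
        # the recorded trace is the average of n_shots repeated measurements
        shots = [
            simulate_pa_signal(
                params,
                ts=spec.ts,
                n_samples=n_samples,
                delay=sample.delay,
                noise_snr_db=sample.snr_db,
                seed=int(s),
            ).samples
            for s in shot_seeds
        ]
        sig = PASignal(np.mean(shots, axis=0), spec.ts, meta=meta)
        signals.append(sig)
        rows.append({
            "sample_id": sample.sample_id,
            "MW": sample.mw,
            "concentration": sample.concentration,
            "zeta": sample.zeta,
            "omega_n_rad_s": sample.omega_n,
            "f_n_mhz": sample.omega_n / (2e6 * np.pi),
            "gain_Vs": sample.gain,
            "delay_us": sample.delay * 1e6,
            "D_mm": sample.D,
            "snr_db": sample.snr_db,
            "n_shots": n_shots,
            "noise_seed": int(shot_seeds[0]),
        })
    return signals, pd.DataFrame(rows)
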