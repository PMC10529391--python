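"""Time-domain descriptors of a photoacoustic trace.

Three quantities summarise a PA measurement of a hydrogel phantom: the
peak-to-peak amplitude (proportional to optical absorption), the arrival
time ``t_a`` of the pressure wave at the transducer, and the speed of sound
``c = D / t_a`` obtained from the sample diameter ``D``.  Amplitudes are
volts internally and reported in mV; times are seconds internally and
reported in microseconds, matching the usual oscilloscope conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import PASignal

__all__ = [
    "SampleGeometry",
    "PAFeatures",
    "peak_to_peak",
    "arrival_time",
    "speed_of_sound",
    "compute_features",
    "write_feature_table",
    "NoArrivalError",
]


class NoArrivalError(ValueError):
    """Raised when no acoustic event is detectable in the record."""


@dataclass(frozen=True)
class SampleGeometry:
    """Hydrogel cross-section dimensions in millimetres.

    ``D`` is the outer diameter; ``d1`` and ``d3`` are the two wall
    thicknesses and ``d2`` the internal diameter, so ``d1 + d2 + d3``
    should approximate ``D`` within the measurement spread.
    """

    D: float
    d1: Optional[float] = None
    d2: Optional[float] = None
    d3: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.D > 0:
            raise ValueError(f"diameter must be positive, got {self.D}")


@dataclass(frozen=True)
class PAFeatures:
    """Per-sample feature triple: amplitude (mV), arrival time (us), c (m/s)."""

    amplitude_pp: float
    t_a: float
    c: float
    arrival_method: str = "threshold"


def peak_to_peak(signal: PASignal, window: Optional[Tuple[float, float]] = None) -> float:
    """Peak-to-peak amplitude (max - min) within a time window.

    ``window`` is ``(t_start, t_end)`` in seconds; by default the window
    runs from the detected arrival time to the end of the record (the whole
    record when no arrival is detectable, e.g. a flat trace).
    """
    t = signal.times
    if window is None:
        try:
            start = arrival_time(signal)
        except NoArrivalError:
            start = t[0]
        window = (start, t[-1])
    lo, hi = window
    mask = (t >= lo) & (t <= hi)
    if not np.any(mask):
        raise ValueError(f"window {window} contains no samples")
    seg = signal.samples[mask]
    return float(seg.max() - seg.min())


def arrival_time(
    signal: PASignal,
    method: str = "threshold",
    threshold_fraction: float = 0.1,
) -> float:
    """Arrival time of the pressure wave.

    The default ``threshold`` method reports the first instant at which
    ``|y|`` exceeds ``threshold_fraction`` of the global peak; the
    ``first-peak`` method reports the first local extremum of ``|y|`` above
    that level.  A detectable event is required: the global peak must
    exceed five times the baseline noise RMS, the baseline being the first
    10% of the record.

    Returns the arrival time in seconds (on the signal's own time axis).
    """
    y = signal.samples
    absy = np.abs(y)
    peak = float(absy.max())
    n_base = max(1, y.size // 10)
    baseline_rms = float(np.sqrt(np.mean(y[:n_base] ** 2)))
    if peak == 0.0 or (baseline_rms > 0 and peak <= 5.0 * baseline_rms):
        raise NoArrivalError(
            f"no acoustic event: peak {peak:.3g} V does not exceed 5x baseline RMS "
            f"({baseline_rms:.3g} V)"
        )
    level = threshold_fraction * peak
    if method == "threshold":
        idx = int(np.argmax(absy >= level))
    elif method == "first-peak":
        peaks, _ = find_peaks(absy, height=level)
        if peaks.size == 0:
            raise NoArrivalError("no local extremum above the detection level")
        idx = int(peaks[0])
    else:
        raise ValueError(f"unknown arrival method {method!r}")
    return float(signal.t0 + idx * signal.ts)


def speed_of_sound(D_mm: float, t_a_us: float) -> float:
    """Speed of sound ``c = D / t_a`` in m/s from mm and microseconds.

    1 mm / 1 us = 1000 m/s.
    """
    if D_mm <= 0 or t_a_us <= 0:
        raise ValueError(f"D and t_a must be positive, got D={D_mm}, t_a={t_a_us}")
    return D_mm / t_a_us * 1000.0


def compute_features(
    signal: PASignal,
    geometry: SampleGeometry,
    arrival_method: str = "threshold",
    threshold_fraction: float = 0.1,
) -> PAFeatures:
    """Full feature triple for one trace: amplitude (mV), t_a (us), c (m/s)."""
    t_a = arrival_time(signal, method=arrival_method, threshold_fraction=threshold_fraction)
    amp = peak_to_peak(signal, window=(t_a, signal.times[-1]))
    return PAFeatures(
        amplitude_pp=amp * 1e3,
        t_a=t_a * 1e6,
        c=speed_of_sound(geometry.D, t_a * 1e6),
        arrival_method=arrival_method,
    )


def write_feature_table(rows: Iterable[dict], path) -> pd.DataFrame:
    """Write a per-sample feature table as CSV.

    Each row is a mapping with keys ``sample_id, MW, concentration, D_mm,
    ta_us, c_m_s, amplitude_mV``; speeds are rounded to integer m/s for
    reporting.
    """
    df = pd.DataFrame(list(rows), columns=[
        "sample_id", "MW", "concentration", "D_mm", "ta_us", "c_m_s", "amplitude_mV",
    ])
    df["c_m_s"] = df["c_m_s"].round().astype("Int64")
    df.to_csv(path, index=False)
    return df
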