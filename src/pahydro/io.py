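"""Signal file I/O and run configuration.

Traces travel as two-column time/amplitude tables (CSV or TSV, the usual
oscilloscope export dialect): time in seconds, amplitude in volts, header
optional.  The time grid must be uniform; the sampling interval is taken
as the median time step and a relative deviation beyond 1e-6 is rejected.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core import PASignal, SampleMeta

__all__ = [
    "read_signal",
    "write_signal",
    "RunConfig",
    "NonUniformGridError",
]

_GRID_RTOL = 1e-6


class NonUniformGridError(ValueError):
    """Raised when the time axis of an input table is not uniform."""


def read_signal(path, dialect: Optional[str] = None, meta: Optional[SampleMeta] = None) -> PASignal:
    """Read a two-column (time_s, amplitude_V) table into a :class:`PASignal`.

    ``dialect`` may be ``"csv"`` or ``"tsv"``; by default the separator is
    sniffed.  Requires at least 10 rows and a uniform time grid within a
    relative tolerance of 1e-6 on the time step.
    """
    sep = {"csv": ",", "tsv": "\t", None: None}[dialect]
    df = pd.read_csv(path, sep=sep, engine="python", comment="#", header=None,
                     skip_blank_lines=True)
    # drop a header row if the first row is not numeric
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().any():
        df = df.iloc[1:]
    if df.shape[1] < 2:
        raise ValueError(f"expected two columns (time, amplitude) in {path}")
    t = pd.to_numeric(df.iloc[:, 0]).to_numpy(dtype=float)
    y = pd.to_numeric(df.iloc[:, 1]).to_numpy(dtype=float)
    if t.size < 10:
        raise ValueError(f"signal table must have at least 10 rows, got {t.size}")
    dt = np.diff(t)
    ts = float(np.median(dt))
    if ts <= 0:
        raise NonUniformGridError("time axis is not increasing")
    if np.max(np.abs(dt - ts)) > _GRID_RTOL * ts:
        raise NonUniformGridError(
            f"non-uniform time grid: max step deviation "
            f"{np.max(np.abs(dt - ts)) / ts:.2e} exceeds relative tolerance {_GRID_RTOL}"
        )
    return PASignal(y, ts, t0=float(t[0]), meta=meta)


def write_signal(signal: PASignal, path) -> None:
    """Write a trace as a CSV with columns ``time_s, amplitude_V``.

    Values are written with 12 significant digits so that a read/write
    round trip preserves the samples to that precision.
    """
    df = pd.DataFrame({"time_s": signal.times, "amplitude_V": signal.samples})
    df.to_csv(path, index=False, float_format="%.12e")


@dataclass
class RunConfig:
    """Flat, YAML-serializable configuration of a processing run."""

    version: int = 1
    decimation_target_spp: float = 30.0
    hankel_i: int = 20
    order: Optional[int] = None  # None = automatic singular-value gap
    arrival_method: str = "threshold"
    arrival_threshold: float = 0.1
    mc_photons: int = 100_000
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.decimation_target_spp < 4:
            raise ValueError("decimation target must be at least 4 samples per period")
        if self.hankel_i < 2:
            raise ValueError("hankel_i must be >= 2")
        if self.order is not None and self.order < 1:
            raise ValueError("fixed order must be >= 1")
        if not 0 < self.arrival_threshold < 1:
            raise ValueError("arrival threshold must be a fraction in (0, 1)")
        if self.mc_photons < 1000:
            raise ValueError("mc_photons must be >= 1000")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        """Short stable hash of the configuration, for log lines."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
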