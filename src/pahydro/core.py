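"""Domain types and the second-order forward model for photoacoustic signals.

A pulsed-laser photoacoustic (PA) measurement of a hydrogel phantom can be
treated as the impulse response of a linear time-invariant second-order
mechanical system: the laser pulse deposits energy almost instantaneously,
and the resulting pressure transient rings down at the sample's natural
frequency ``omega_n`` with damping ratio ``zeta``.  All material constants
entering the underlying wave physics (thermal expansion, heat capacity,
viscosities, the Gruneisen parameter) are lumped into the triple
``(omega_n, zeta, gain)`` because they are not separately identifiable from
a single output trace.

This module provides the in-memory containers used throughout the package
(:class:`PASignal`, :class:`SecondOrderParams`, :class:`StateSpaceModel`)
and the forward model (:func:`simulate_pa_signal`, :func:`discretize`) that
the identification machinery is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import expm

__all__ = [
    "SampleMeta",
    "PASignal",
    "SecondOrderParams",
    "StateSpaceModel",
    "simulate_pa_signal",
    "discretize",
    "UnsupportedRegimeError",
    "AliasingError",
]


class UnsupportedRegimeError(ValueError):
    """Raised when a damping regime outside the underdamped one is requested."""


class AliasingError(ValueError):
    """Raised when the sampling interval cannot resolve the oscillation."""


@dataclass(frozen=True)
class SampleMeta:
    """Descriptor of a hydrogel sample.

    Parameters
    ----------
    mw : str
        Molecular-weight class, ``"MW1"`` or ``"MW2"``.
    concentration : float
        PVA concentration in percent.
    diameter_mm : float, optional
        Outer diameter ``D`` of the sample in millimetres.
    sample_id : str, optional
        Free-form identifier.
    """

    mw: str = "MW1"
    concentration: float = float("nan")
    diameter_mm: Optional[float] = None
    sample_id: Optional[str] = None


@dataclass
class PASignal:
    """Uniformly sampled photoacoustic pressure trace.

    ``samples`` are amplitudes in volts on the exact time grid
    ``t_k = t0 + k * ts``.
    """

    samples: np.ndarray
    ts: float
    t0: float = 0.0
    meta: Optional[SampleMeta] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.ts <= 0:
            raise ValueError(f"sampling interval must be positive, got {self.ts}")
        if self.samples.size == 0:
            raise ValueError("signal must contain at least one sample")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds."""
        return self.t0 + self.ts * np.arange(self.samples.size)

    @property
    def duration(self) -> float:
        return self.ts * (self.samples.size - 1)

    def shifted(self, delta: float) -> "PASignal":
        """Return a copy whose time axis is shifted by ``delta`` seconds."""
        return PASignal(self.samples.copy(), self.ts, self.t0 + delta, self.meta)


@dataclass(frozen=True)
class SecondOrderParams:
    """Modal parameters of the lumped second-order oscillator.

    Attributes
    ----------
    omega_n : float
        Natural frequency in rad/s (> 0).
    zeta : float
        Dimensionless damping ratio.  The PA regime of interest is
        underdamped (``0 <= zeta < 1``); larger values are representable so
        that extraction from an arbitrary identified model never fails, but
        the forward simulator rejects them.
    gain : float
        Impulse magnitude in volt-seconds.  It scales the unit second-order
        impulse response and lumps the optical forcing and thermoelastic
        conversion efficiency.
    """

    omega_n: float
    zeta: float
    gain: float = 1.0

    def __post_init__(self) -> None:
        if not self.omega_n > 0:
            raise ValueError(f"omega_n must be positive, got {self.omega_n}")

    @property
    def underdamped(self) -> bool:
        return 0.0 <= self.zeta < 1.0

    @property
    def omega_d(self) -> float:
        """Damped oscillation frequency ``omega_n * sqrt(1 - zeta^2)`` (rad/s)."""
        if not self.underdamped:
            raise UnsupportedRegimeError(
                f"damped frequency undefined for zeta={self.zeta!r} (need 0 <= zeta < 1)"
            )
        return self.omega_n * np.sqrt(1.0 - self.zeta**2)


@dataclass
class StateSpaceModel:
    """Discrete-time single-output state-space model ``{A, B, C}``.

    The state recursion is ``x[k+1] = A x[k] + B u[k]``, ``y[k] = C x[k]``,
    with sampling interval ``ts``.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    ts: float

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.B = np.asarray(self.B, dtype=float).reshape(-1, 1)
        self.C = np.asarray(self.C, dtype=float).reshape(1, -1)
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError(f"A must be square, got shape {self.A.shape}")
        if self.B.shape != (n, 1) or self.C.shape != (1, n):
            raise ValueError(
                f"inconsistent dimensions: A {self.A.shape}, B {self.B.shape}, C {self.C.shape}"
            )
        if self.ts <= 0:
            raise ValueError(f"sampling interval must be positive, got {self.ts}")

    @property
    def order(self) -> int:
        return self.A.shape[0]

    @property
    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvals(self.A)

    @property
    def stable(self) -> bool:
        """True when all eigenvalues lie strictly inside the unit circle."""
        return bool(np.all(np.abs(self.eigenvalues) < 1.0))

    def impulse_response(self, n_samples: int) -> np.ndarray:
        """Response to a unit discrete impulse ``u[0] = 1`` from rest.

        ``y[0] = 0`` and ``y[k] = C A^(k-1) B`` for ``k >= 1``.
        """
        y = np.zeros(n_samples)
        x = self.B[:, 0].copy()
        for k in range(1, n_samples):
            y[k] = float(self.C[0] @ x)
            x = self.A @ x
        return y

    def free_response(self, x0: np.ndarray, n_samples: int) -> np.ndarray:
        """Output ``y[k] = C A^k x0`` of the unforced system."""
        x = np.asarray(x0, dtype=float).reshape(-1)
        y = np.zeros(n_samples)
        for k in range(n_samples):
            y[k] = float(self.C[0] @ x)
            x = self.A @ x
        return y


def _continuous_matrices(params: SecondOrderParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # companion form of  y'' + 2*zeta*wn*y' + wn^2*y = gain*wn^2*u
    wn, z, g = params.omega_n, params.zeta, params.gain
    A = np.array([[0.0, 1.0], [-wn**2, -2.0 * z * wn]])
    B = np.array([[0.0], [g * wn**2]])
    C = np.array([[1.0, 0.0]])
    return A, B, C


def simulate_pa_signal(
    params: SecondOrderParams,
    ts: float,
    n_samples: int,
    delay: float = 0.0,
    noise_snr_db: Optional[float] = None,
    seed: Optional[int] = None,
    t0: float = 0.0,
    meta: Optional[SampleMeta] = None,
) -> PASignal:
    """Simulate a PA trace as a delayed second-order impulse response.

    The noise-free model is

    .. code-block:: text

        y(t) = gain * (omega_n / sqrt(1 - zeta^2))
               * exp(-zeta * omega_n * (t - delay))
               * sin(omega_n * sqrt(1 - zeta^2) * (t - delay))   for t >= delay

    and zero before the delay.  Optional additive white Gaussian noise is
    scaled so that the signal-to-noise ratio, defined on the RMS of the
    noise-free trace over its support (``t >= delay``), equals
    ``noise_snr_db`` decibels.

    Parameters
    ----------
    params : SecondOrderParams
        Underdamped modal parameters.
    ts : float
        Sampling interval in seconds.  Must satisfy ``omega_n * ts < pi``.
    n_samples : int
        Record length.
    delay : float
        Onset time of the impulse (seconds), e.g. the acoustic arrival time.
    noise_snr_db : float or None
        SNR of the added white Gaussian noise; ``None`` disables noise.
    seed : int or None
        Seed for the noise generator; identical seeds give identical traces.

    Raises
    ------
    UnsupportedRegimeError
        If ``zeta >= 1`` (not underdamped).
    AliasingError
        If ``omega_n * ts >= pi``.
    """
    if not params.underdamped:
        raise UnsupportedRegimeError(
            f"simulation requires an underdamped system (0 <= zeta < 1), got zeta={params.zeta}"
        )
    if ts <= 0:
        raise ValueError(f"sampling interval must be positive, got {ts}")
    if params.omega_n * ts >= np.pi:
        raise AliasingError(
            f"omega_n * ts = {params.omega_n * ts:.3g} >= pi: the oscillation at "
            f"{params.omega_n / (2 * np.pi):.3g} Hz is not resolved by ts = {ts:.3g} s"
        )
    t = t0 + ts * np.arange(int(n_samples))
    tau = t - delay
    y = np.zeros_like(tau)
    on = tau >= 0
    wd = params.omega_d
    sigma = params.zeta * params.omega_n
    amp = params.gain * params.omega_n / np.sqrt(1.0 - params.zeta**2)
    y[on] = amp * np.exp(-sigma * tau[on]) * np.sin(wd * tau[on])
    if noise_snr_db is not None:
        support = y[on]
        rms = float(np.sqrt(np.mean(support**2))) if support.size else 0.0
        noise_rms = rms * 10.0 ** (-noise_snr_db / 20.0)
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_rms, size=y.size)
    return PASignal(y, ts, t0=t0, meta=meta)


def discretize(params: SecondOrderParams, ts: float) -> StateSpaceModel:
    """Exact (matrix-exponential) discretization of the second-order model.

    The returned order-2 model has eigenvalues

    ``lambda = exp((-zeta*omega_n +/- j*omega_n*sqrt(1-zeta^2)) * ts)``

    and its discrete impulse response interpolates the continuous one at the
    sample instants: ``y[k] = gain * h(k*ts)`` with ``h`` the unit
    second-order impulse response.  Round-tripping through
    :func:`pahydro.dynamics.extract_modal_params` recovers ``(omega_n,
    zeta)`` to machine precision.
    """
    if not params.underdamped:
        raise UnsupportedRegimeError(
            f"discretize requires an underdamped system, got zeta={params.zeta}"
        )
    if ts <= 0:
        raise ValueError(f"sampling interval must be positive, got {ts}")
    Ac, Bc, Cc = _continuous_matrices(params)
    Ad = expm(Ac * ts)
    # impulse at k=0 must place the state at x(ts) = e^{Ac ts} Bc so that
    # y[k] = C Ad^{k-1} B = C e^{Ac k ts} Bc, the sampled continuous response
    Bd = Ad @ Bc
    return StateSpaceModel(Ad, Bd, Cc, ts)
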