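"""Modal-parameter extraction, goodness of fit, and concentration trends.

Given an identified discrete-time system matrix ``A`` with sampling
interval ``Ts``, the continuous-time modal parameters follow from the
principal branch of the complex logarithm of the selected eigenvalue
``lambda``::

    omega_n = |ln(lambda)| / Ts
    zeta    = -cos(angle(ln(lambda)))

For a conjugate pair ``lambda = exp((-sigma +/- j*omega_d) Ts)`` this gives
``omega_n = sqrt(sigma^2 + omega_d^2)`` and ``zeta = sigma / omega_n``, the
familiar pole geometry of a second-order system.  Fit quality is measured
by the NRMSE fit percentage, and the dependence of the modal parameters on
PVA concentration is summarised with low-order polynomial trend fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import SecondOrderParams

__all__ = [
    "TrendFit",
    "extract_modal_params",
    "nrmse",
    "physical_ratios",
    "fit_concentration_trend",
    "SingularPoleError",
    "ConstantSignalError",
]


class SingularPoleError(ValueError):
    """Raised when the selected eigenvalue is zero (log undefined)."""


class ConstantSignalError(ValueError):
    """Raised when the NRMSE denominator vanishes (constant reference)."""


def _select_eigenvalue(eigenvalues: np.ndarray) -> complex:
    """Pick the reporting eigenvalue: positive imaginary part preferred,
    dominant magnitude as tie-break."""
    eig = np.asarray(eigenvalues, dtype=complex).ravel()
    pos = eig[eig.imag > 0]
    candidates = pos if pos.size else eig[np.abs(eig.imag) <= np.finfo(float).eps * np.abs(eig).max(initial=1.0)]
    if candidates.size == 0:
        # only negative-imaginary eigenvalues (shouldn't happen for real A)
        candidates = eig.conj()
    lam = candidates[np.argmax(np.abs(candidates))]
    return complex(lam)


def extract_modal_params(A: np.ndarray, ts: float) -> SecondOrderParams:
    """Natural frequency and damping ratio from a discrete system matrix.

    Parameters
    ----------
    A : (n, n) array
        Identified discrete-time system matrix.
    ts : float
        Sampling interval in seconds.

    Returns
    -------
    SecondOrderParams
        ``omega_n`` in rad/s and dimensionless ``zeta``; the gain slot is
        set to 1 because the amplitude scale is not encoded in ``A``.

    Notes
    -----
    Among the eigenvalues of ``A`` the one with positive imaginary part is
    used (conjugate pairs carry identical modal parameters).  A real
    eigenvalue on the negative axis sits on the branch cut of the logarithm
    and triggers a warning; a real pole in ``(0, 1)`` maps to ``zeta = 1``,
    the critically damped limit.
    """
    if ts <= 0:
        raise ValueError(f"sampling interval must be positive, got {ts}")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    lam = _select_eigenvalue(np.linalg.eigvals(A))
    if lam == 0:
        raise SingularPoleError("eigenvalue at the origin: modal parameters undefined")
    if lam.imag == 0 and lam.real < 0:
        warnings.warn(
            "eigenvalue on the negative real axis: principal-branch log is "
            "discontinuous there; modal parameters may be unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    log_lam = np.log(complex(lam))
    omega_n = abs(log_lam) / ts
    zeta = -np.cos(np.angle(log_lam))
    return SecondOrderParams(omega_n=omega_n, zeta=float(zeta))


def nrmse(y_measured: np.ndarray, y_model: np.ndarray) -> float:
    """NRMSE fit percentage between a measured trace and a model output.

    ``100 * (1 - ||y_meas - y_model|| / ||y_meas - mean(y_meas)||)``: 100
    means perfect reproduction, 0 is no better than the mean, and negative
    values indicate a fit worse than the mean predictor.
    """
    y = np.asarray(y_measured, dtype=float).ravel()
    yhat = np.asarray(y_model, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError(f"length mismatch: {y.size} vs {yhat.size}")
    if y.size < 2:
        raise ValueError("need at least two samples")
    denom = np.linalg.norm(y - y.mean())
    if denom == 0:
        raise ConstantSignalError("reference signal is constant: NRMSE undefined")
    return float((1.0 - np.linalg.norm(y - yhat) / denom) * 100.0)


def physical_ratios(params: SecondOrderParams) -> tuple[float, float]:
    """Lumped stiffness and damping ratios of the mechanical analogue.

    Returns ``(k/m, b/m) = (omega_n**2, 2*zeta*omega_n)`` in s^-2 and s^-1.
    The individual ``k``, ``b``, ``m`` are not identifiable from one trace.
    """
    return params.omega_n**2, 2.0 * params.zeta * params.omega_n


@dataclass
class TrendFit:
    """Polynomial trend of a modal parameter against PVA concentration.

    ``coefficients`` are ordered highest degree first (numpy convention).
    """

    degree: int
    coefficients: np.ndarray
    r_squared: float
    x: np.ndarray
    y: np.ndarray

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.polyval(self.coefficients, np.asarray(x, dtype=float))

    @property
    def slope(self) -> float:
        """Leading first-order coefficient (the slope for ``degree == 1``)."""
        return float(self.coefficients[-2])


def fit_concentration_trend(
    concentrations: np.ndarray, values: np.ndarray, degree: int = 1
) -> TrendFit:
    """Least-squares polynomial fit of a parameter against concentration.

    The damping ratio of PVA hydrogels rises approximately linearly with
    concentration (``degree=1``) while the natural frequency falls along a
    quadratic (``degree=2``); the returned ``r_squared`` quantifies how well
    the chosen degree explains the data.
    """
    x = np.asarray(concentrations, dtype=float).ravel()
    y = np.asarray(values, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("concentrations and values must have equal length")
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if x.size < degree + 2:
        raise ValueError(
            f"under-determined trend fit: need >= {degree + 2} points for degree {degree}, got {x.size}"
        )
    coeffs = np.polyfit(x, y, degree)
    resid = y - np.polyval(coeffs, x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return TrendFit(degree=degree, coefficients=coeffs, r_squared=r2, x=x, y=y)
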