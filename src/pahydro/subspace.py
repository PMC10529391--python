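"""Subspace state-space identification (N4SID) for photoacoustic traces.

The measured trace is arranged in a block Hankel matrix split into past and
future partitions; the future outputs are projected onto the row space of
the past (an orthogonal projection in the output-only case, the oblique
projection along a measured input's row space otherwise).  An SVD of the
projection reveals the model order as a gap in the singular-value spectrum,
its truncated factors give the extended observability matrix
``Gamma_i = U1 S1^(1/2)`` and the state sequences, and a final linear
least-squares regression yields the system matrices ``{A, C}``.  Because a
PA measurement records no input — the laser pulse is treated as an
impulse — ``B`` is recovered from the estimated initial state of the
ring-down instead of from an input regression.

The public entry point is :func:`n4sid_fit`; the intermediate operations
(:func:`build_hankel`, :func:`orthogonal_project`, :func:`estimate_order`)
are exposed for testing and diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import PASignal, SecondOrderParams, StateSpaceModel
from .dynamics import extract_modal_params, nrmse

__all__ = [
    "HankelData",
    "SubspaceDecomposition",
    "IdentificationResult",
    "N4SIDConfig",
    "build_hankel",
    "orthogonal_project",
    "estimate_order",
    "n4sid_fit",
    "extended_observability",
    "controllability",
    "impulse_toeplitz",
    "SignalTooShortError",
    "NoDynamicsError",
]

_RCOND = 1e-12  # relative pseudo-inverse cutoff used throughout


class SignalTooShortError(ValueError):
    """Raised when a record cannot fill the requested Hankel matrix."""


class NoDynamicsError(ValueError):
    """Raised when the data carry no identifiable dynamics (order 0)."""


@dataclass
class HankelData:
    """Past/future block Hankel partition of a scalar output record.

    The stacked matrix ``[Yp; Yf]`` has entry ``y[r + c]`` at row ``r``,
    column ``c``; ``Yp_plus``/``Yf_minus`` is the shifted partition with the
    first row of ``Yf`` moved to the bottom of ``Yp``.
    """

    Yp: np.ndarray
    Yf: np.ndarray
    Yp_plus: np.ndarray
    Yf_minus: np.ndarray
    i: int
    j: int


@dataclass
class SubspaceDecomposition:
    """Intermediate quantities of the subspace projection step."""

    Oi: np.ndarray
    singular_values: np.ndarray
    U1: np.ndarray
    S1: np.ndarray
    V1: np.ndarray
    Gamma_i: np.ndarray
    Xi: np.ndarray
    Xi_next: np.ndarray


@dataclass
class IdentificationResult:
    """Output of :func:`n4sid_fit`.

    ``model`` is the identified discrete-time ``{A, B, C}`` at the
    effective (possibly decimated) sampling interval; ``x0`` is the
    estimated state at the start of the fitted window, from which ``B`` is
    taken; ``nrmse_percent`` compares the model's free response from ``x0``
    with the preprocessed measured segment it was fitted to.
    """

    model: StateSpaceModel
    singular_values: np.ndarray
    order: int
    eigenvalues: np.ndarray
    nrmse_percent: float
    modal: SecondOrderParams
    x0: np.ndarray
    stable: bool
    decimation_factor: int = 1
    window: tuple = (0, 0)
    decomposition: Optional[SubspaceDecomposition] = None
    fitted_segment: Optional[np.ndarray] = None
    predicted_segment: Optional[np.ndarray] = None


@dataclass
class N4SIDConfig:
    """Tunable knobs of the identification pipeline.

    Attributes
    ----------
    i : int
        Hankel block rows (defaults to 20, far above the expected order 2
        and far below the record length; shrunk automatically when the
        windowed record is short).
    order : int or None
        Fixed model order; ``None`` selects it from the singular-value gap.
    target_samples_per_period : float
        Decimation target.  Oscilloscope records oversample the transducer
        band enormously, which ill-conditions the Hankel matrix; the trace
        is low-pass filtered and decimated until the dominant oscillation
        has roughly 20-50 samples per period.
    window : str
        ``"arrival"`` fits only the ring-down segment (onset at 10% of the
        global peak, end where the one-period envelope falls below 2% of
        the peak or into the noise floor); ``"full"`` uses the whole record.
    """

    i: int = 20
    order: Optional[int] = None
    target_samples_per_period: float = 30.0
    sv_threshold_ratio: float = 1e-2
    window: str = "arrival"
    arrival_threshold: float = 0.1
    detrend: bool = True
    keep_decomposition: bool = False


def build_hankel(signal: PASignal, i: int, j: Optional[int] = None) -> HankelData:
    """Arrange a record in past/future block Hankel matrices.

    ``Yp`` holds rows ``0..i-1`` and ``Yf`` rows ``i..2i-1`` of the Hankel
    matrix of the samples; ``j`` defaults to ``len(signal) - 2i + 1`` so
    that every sample is used.
    """
    y = signal.samples
    if i < 2:
        raise ValueError(f"need at least i=2 block rows, got {i}")
    if j is None:
        j = y.size - 2 * i + 1
    if j < 1 or 2 * i + j - 1 > y.size:
        raise SignalTooShortError(
            f"signal of length {y.size} cannot fill a Hankel matrix with i={i}, "
            f"j={j}: need at least {2 * i + max(j, 1) - 1} samples "
            f"(minimum 2*i = {2 * i} for j=1)"
        )
    idx = np.arange(2 * i)[:, None] + np.arange(j)[None, :]
    H = y[idx]
    return HankelData(
        Yp=H[:i], Yf=H[i : 2 * i], Yp_plus=H[: i + 1], Yf_minus=H[i + 1 : 2 * i], i=i, j=j
    )


def orthogonal_project(
    Yf: np.ndarray, Wp: np.ndarray, Uf: Optional[np.ndarray] = None
) -> np.ndarray:
    """Project the rows of ``Yf`` onto the row space of ``Wp``.

    With ``Uf=None`` (the output-only default) this is the orthogonal
    projection ``Yf * Wp^T * (Wp Wp^T)^+ * Wp``; with a future-input block
    ``Uf`` it is the oblique projection of ``Yf`` onto the row space of
    ``Wp`` along the row space of ``Uf``.  Rank deficiency is handled by
    the pseudo-inverse.
    """
    Yf = np.atleast_2d(np.asarray(Yf, dtype=float))
    Wp = np.atleast_2d(np.asarray(Wp, dtype=float))
    if Yf.shape[1] != Wp.shape[1]:
        raise ValueError(f"column mismatch: Yf has {Yf.shape[1]}, Wp has {Wp.shape[1]}")
    if Uf is None:
        G = Yf @ np.linalg.pinv(Wp, rcond=_RCOND)
        return G @ Wp
    Uf = np.atleast_2d(np.asarray(Uf, dtype=float))
    if Uf.shape[1] != Wp.shape[1]:
        raise ValueError(f"column mismatch: Uf has {Uf.shape[1]}, Wp has {Wp.shape[1]}")
    # project both factors onto the orthogonal complement of row(Uf), then
    # reconstruct along row(Wp):  Yf /_{Uf} Wp = [Yf P][Wp P]^+ Wp
    P = np.eye(Uf.shape[1]) - np.linalg.pinv(Uf, rcond=_RCOND) @ Uf
    return (Yf @ P) @ np.linalg.pinv(Wp @ P, rcond=_RCOND) @ Wp


def estimate_order(singular_values: np.ndarray, threshold_ratio: float = 1e-2) -> int:
    """Model order from the largest relative gap in the singular values.

    Only leading singular values with ``s_k / s_1 >= threshold_ratio`` are
    candidate orders; among them the index maximising ``s_k / s_{k+1}`` is
    returned.  An all-zero spectrum yields order 0 with a warning.
    """
    s = np.asarray(singular_values, dtype=float).ravel()
    if s.size == 0 or s[0] <= 0:
        warnings.warn("all singular values are zero: no dynamics", RuntimeWarning, stacklevel=2)
        return 0
    if np.any(np.diff(s) > 0) or np.any(s < 0):
        raise ValueError("singular values must be non-negative and non-increasing")
    if s.size == 1:
        return 1
    ratios = s / s[0]
    candidates = [k for k in range(1, s.size) if ratios[k - 1] >= threshold_ratio]
    if not candidates:
        return 1
    gaps = [(s[k - 1] / s[k] if s[k] > 0 else np.inf) for k in candidates]
    return candidates[int(np.argmax(gaps))]


def extended_observability(model: StateSpaceModel, i: int) -> np.ndarray:
    """Stack ``[C; CA; ...; CA^{i-1}]`` (diagnostic)."""
    rows = []
    r = model.C.copy()
    for _ in range(i):
        rows.append(r.copy())
        r = r @ model.A
    return np.vstack(rows)


def controllability(model: StateSpaceModel, i: int) -> np.ndarray:
    """Reversed controllability matrix ``[A^{i-1}B ... AB B]`` (diagnostic)."""
    cols = []
    c = model.B.copy()
    for _ in range(i):
        cols.append(c.copy())
        c = model.A @ c
    return np.hstack(cols[::-1])


def impulse_toeplitz(model: StateSpaceModel, k: int) -> np.ndarray:
    """Lower-triangular Toeplitz matrix of impulse-response coefficients
    (diagnostic): zero diagonal, ``CA^{r-c-1}B`` below it."""
    h = np.zeros(k)
    x = model.B[:, 0].copy()
    for m in range(1, k):
        h[m] = float(model.C[0] @ x)
        x = model.A @ x
    T = np.zeros((k, k))
    for r in range(k):
        for c in range(r):
            T[r, c] = h[r - c]
    return T


def _dominant_period_samples(y: np.ndarray) -> float:
    """Samples per period of the dominant spectral component (>= 2)."""
    n = y.size
    spec = np.abs(np.fft.rfft(y))
    spec[0] = 0.0  # ignore DC
    k = int(np.argmax(spec))
    if k == 0:
        return float(n)
    return n / k


def _decimate(y: np.ndarray, q: int) -> np.ndarray:
    """Boxcar (block-average) decimation by an integer factor.

    Averaging q consecutive samples reduces white-noise variance by
    exactly q — the same as an ideal low-pass to the new Nyquist band —
    while the filter's support of q raw samples confines onset transients
    to a single decimated sample.  The boxcar's passband droop at the
    oscillation frequency (< 1% at 20+ samples per period) rescales mode
    amplitudes only; the eigenvalues that carry ``omega_n`` and ``zeta``
    are invariant under any LTI filtering.
    """
    n = (y.size // q) * q
    return y[:n].reshape(-1, q).mean(axis=1)


def _decimation_factor(spp: float, target: float) -> int:
    q = int(spp // target)
    return max(q, 1)


def _ring_down_window(
    y: np.ndarray, spp: float, arrival_threshold: float
) -> tuple[int, int, float]:
    """Indices [start, end) of the ring-down segment plus the noise floor.

    Start: first sample with |y| above ``arrival_threshold`` of the peak.
    End: first point after the peak where the one-period running maximum of
    |y| drops below max(2% of peak, 1.5x the median envelope, a noise-floor
    proxy), plus one period of margin.  The third return value is the
    median envelope as a fraction of the peak (a noise-floor estimate,
    since the envelope of an impulse-like record is baseline-dominated).
    """
    absy = np.abs(y)
    peak = absy.max()
    start = int(np.argmax(absy >= arrival_threshold * peak))
    # a half-period running maximum bridges the zero crossings of the
    # oscillation without padding the ring-down with a noise-only tail
    size = max(3, int(round(spp / 2)))
    from scipy.ndimage import maximum_filter1d

    env = maximum_filter1d(absy, size=size)
    med_env = float(np.median(env))
    floor = max(0.02 * peak, 1.5 * med_env)
    ipeak = int(np.argmax(absy))
    below = np.nonzero(env[ipeak:] < floor)[0]
    end = ipeak + int(below[0]) if below.size else y.size
    # at least three oscillation periods: heavily damped ring-downs would
    # otherwise leave too few Hankel columns for a stable estimate
    end = max(end, start + 3 * int(round(spp)))
    return start, min(end, y.size), med_env / peak


def _estimate_initial_state(
    A: np.ndarray, C: np.ndarray, y: np.ndarray, max_rows: int = 2000
) -> np.ndarray:
    """Least-squares initial state of the free response ``y[k] = C A^k x0``."""
    n = A.shape[0]
    m = min(y.size, max_rows)
    Obs = np.zeros((m, n))
    r = C.reshape(1, -1).copy()
    for k in range(m):
        Obs[k] = r[0]
        r = r @ A
        if not np.all(np.isfinite(r)):  # unstable estimate: stop stacking
            Obs = Obs[: k + 1]
            m = k + 1
            break
    x0, *_ = np.linalg.lstsq(Obs, y[:m], rcond=_RCOND)
    return x0


def n4sid_fit(
    signal: PASignal,
    i: Optional[int] = None,
    order: Optional[int] = None,
    config: Optional[N4SIDConfig] = None,
    u: Optional[np.ndarray] = None,
) -> IdentificationResult:
    """Identify a discrete-time state-space model from a PA trace.

    Pipeline: DC removal -> low-pass decimation to ~30 samples per period
    -> ring-down windowing -> block Hankel -> projection of future outputs
    onto past outputs -> SVD truncation at the selected order ->
    ``Gamma_i = U1 S1^(1/2)`` -> state sequences by pseudo-inverse ->
    least-squares regression for ``{A, C}`` -> initial-state estimate for
    ``B`` -> NRMSE of the re-simulated response against the fitted segment.

    Parameters
    ----------
    signal : PASignal
        Measured trace.
    i : int, optional
        Hankel block rows (default from ``config``, 20).
    order : int, optional
        Fixed model order; default: automatic singular-value-gap selection.
    config : N4SIDConfig, optional
        Preprocessing and numerical settings.
    u : array, optional
        Measured input sequence aligned with the signal.  When given, the
        oblique projection along the future-input row space is used and
        ``B`` comes from the state regression; by default the record is
        treated as an impulse response and no input is required.

    Raises
    ------
    NoDynamicsError
        For records with no identifiable dynamics (e.g. all zero).
    """
    cfg = config or N4SIDConfig()
    if i is not None:
        cfg = N4SIDConfig(**{**cfg.__dict__, "i": i})
    if order is not None:
        cfg = N4SIDConfig(**{**cfg.__dict__, "order": order})

    y = signal.samples.astype(float)
    if cfg.detrend:
        # median, not mean: an impulse response spends most samples near the
        # baseline, so the median estimates the DC offset without injecting
        # a spurious constant mode the way mean removal would
        y = y - np.median(y)
    if not np.any(y != 0.0):
        raise NoDynamicsError("signal is constant: no dynamics to identify")

    # --- decimate to a sensible number of samples per period -------------
    spp = _dominant_period_samples(y)
    q = _decimation_factor(spp, cfg.target_samples_per_period)
    if q > 1:
        y = _decimate(y, q)
        if u is not None:
            u = _decimate(np.asarray(u, dtype=float), q)
    ts_eff = signal.ts * q
    spp_eff = spp / q

    # --- window the ring-down --------------------------------------------
    if cfg.window == "arrival":
        start, end, _ = _ring_down_window(y, spp_eff, cfg.arrival_threshold)
        if q > 1:
            # the decimated sample straddling the onset averages pre-onset
            # baseline with signal; it belongs to neither regime
            start += 1
    else:
        start, end = 0, y.size
    yw = y[start:end]
    uw = None if u is None else np.asarray(u, dtype=float)[start:end]

    # --- Hankel + projection ----------------------------------------------
    i_eff = min(cfg.i, yw.size // 4)
    if i_eff < 2:
        raise SignalTooShortError(
            f"windowed record of {yw.size} samples is too short for identification "
            f"(need at least 8 = 4 * i_min samples)"
        )
    hank = build_hankel(PASignal(yw, ts_eff), i_eff)
    if uw is not None:
        uh = build_hankel(PASignal(uw, ts_eff), i_eff, hank.j)
        Wp = np.vstack([uh.Yp, hank.Yp])
        Oi = orthogonal_project(hank.Yf, Wp, Uf=uh.Yf)
        O_next = orthogonal_project(
            hank.Yf_minus, np.vstack([uh.Yp_plus, hank.Yp_plus]), Uf=uh.Yf_minus
        )
    else:
        Oi = orthogonal_project(hank.Yf, hank.Yp)
        O_next = orthogonal_project(hank.Yf_minus, hank.Yp_plus)

    U, s, Vt = np.linalg.svd(Oi, full_matrices=False)
    n = cfg.order if cfg.order is not None else estimate_order(s, cfg.sv_threshold_ratio)
    if n < 1:
        raise NoDynamicsError("selected model order is 0: no dynamics to identify")
    n = min(n, s.size)

    U1, S1, V1 = U[:, :n], np.diag(s[:n]), Vt[:n].T
    Gamma_i = U1 @ np.sqrt(S1)
    Xi = np.linalg.pinv(Gamma_i, rcond=_RCOND) @ Oi
    Gamma_up = Gamma_i[:-1]  # one block row (scalar output) shorter
    Xi_next = np.linalg.pinv(Gamma_up, rcond=_RCOND) @ O_next

    # --- least-squares regression for {A, C} (and B with measured input) --
    Yi = hank.Yf[0:1, :]  # outputs y_i ... y_{i+j-1}
    F = np.vstack([Xi_next, Yi])
    if uw is not None:
        Ui = uh.Yf[0:1, :]
        M = np.vstack([Xi, Ui])
    else:
        M = Xi
    Theta = F @ np.linalg.pinv(M, rcond=_RCOND)
    A = Theta[:n, :n]
    C = Theta[n:, :n]
    if uw is not None:
        B = Theta[:n, n:].reshape(n, 1)
    else:
        B = None

    # --- initial state, B, fit quality ------------------------------------
    x0 = _estimate_initial_state(A, C, yw)
    if B is None:
        # impulse-response convention: an impulse one step before the window
        # start would place the state at x0, so B = x0
        B = x0.reshape(n, 1)
    model = StateSpaceModel(A, B, C, ts_eff)
    yhat = model.free_response(x0, yw.size)
    fit = nrmse(yw, yhat)
    modal = extract_modal_params(A, ts_eff)
    eig = np.linalg.eigvals(A)
    stable = bool(np.all(np.abs(eig) < 1.0))
    if not stable:
        warnings.warn(
            "identified model is unstable (|eigenvalue| >= 1); result flagged",
            RuntimeWarning,
            stacklevel=2,
        )
    decomp = (
        SubspaceDecomposition(Oi, s, U1, S1, V1, Gamma_i, Xi, Xi_next)
        if cfg.keep_decomposition
        else None
    )
    return IdentificationResult(
        model=model,
        singular_values=s,
        order=n,
        eigenvalues=eig,
        nrmse_percent=fit,
        modal=modal,
        x0=x0,
        stable=stable,
        decimation_factor=q,
        window=(start, end),
        decomposition=decomp,
        fitted_segment=yw,
        predicted_segment=yhat,
    )
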