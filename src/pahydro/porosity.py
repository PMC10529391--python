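"""Pore-size statistics and simple physical formulas for PVA hydrogels.

Pore diameters (micrometres), extracted upstream from binarized microscope
images, are binned into fixed decade bins spanning 0-80 um and the
resulting histogram is fitted with a scaled LogNormal probability density.
The module also houses the elementary characterization formulas: density
``rho = m / V``, Young's modulus ``E = sigma / epsilon`` and the PVA
powder weight needed for a target concentration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import lognorm

__all__ = [
    "PoreHistogram",
    "LogNormalFit",
    "bin_pores",
    "fit_lognormal",
    "density",
    "elastic_modulus",
    "pva_weight",
    "read_pore_diameters",
    "write_histogram_summary",
    "FitConvergenceError",
]

DEFAULT_EDGES = np.arange(0.0, 90.0, 10.0)  # 0,10,...,80 um


class FitConvergenceError(RuntimeError):
    """Raised when the LogNormal curve fit fails to converge."""


@dataclass
class PoreHistogram:
    """Pore-diameter histogram on half-open bins ``[lo, hi)`` in um."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_out_of_range: int = 0
    n_samples_averaged: int = 1

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.size != self.bin_edges.size - 1:
            raise ValueError("counts length must be number of edges minus one")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def scaled(self, k: float) -> "PoreHistogram":
        return PoreHistogram(self.bin_edges.copy(), self.counts * k,
                             self.n_out_of_range, self.n_samples_averaged)


@dataclass
class LogNormalFit:
    """Scaled LogNormal fit of a pore histogram.

    The fitted curve is ``scale * pdf(x; mu, sigma)`` where ``pdf`` is the
    LogNormal density with log-scale location ``mu`` and shape ``sigma``.
    """

    mu: float
    sigma: float
    scale: float
    r_squared: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.scale * lognorm.pdf(np.asarray(x, dtype=float), s=self.sigma,
                                        scale=np.exp(self.mu))

    @property
    def median_diameter(self) -> float:
        """Median pore diameter ``exp(mu)`` in um."""
        return float(np.exp(self.mu))


def bin_pores(
    diameters: Sequence[float],
    edges: Optional[np.ndarray] = None,
    n_samples_averaged: int = 1,
) -> PoreHistogram:
    """Bin pore diameters into half-open bins ``[lo, hi)``.

    Diameters below the first edge or at/above the last are not binned;
    they are counted in ``n_out_of_range`` so that
    ``sum(counts) + n_out_of_range == len(diameters)``.
    """
    edges = DEFAULT_EDGES if edges is None else np.asarray(edges, dtype=float)
    d = np.asarray(list(diameters), dtype=float)
    if d.size == 0:
        return PoreHistogram(edges, np.zeros(edges.size - 1), 0, n_samples_averaged)
    # digitize with right=False gives k such that edges[k-1] <= d < edges[k]
    idx = np.digitize(d, edges, right=False)
    in_range = (idx >= 1) & (idx <= edges.size - 1)
    counts = np.bincount(idx[in_range] - 1, minlength=edges.size - 1).astype(float)
    return PoreHistogram(edges, counts, int(np.count_nonzero(~in_range)), n_samples_averaged)


def fit_lognormal(hist: PoreHistogram) -> LogNormalFit:
    """Least-squares LogNormal fit of histogram counts at bin midpoints.

    The scaled LogNormal density is fitted to the counts by nonlinear least
    squares; ``r_squared`` measures the explained count variance.  At least
    four non-empty bins are required.
    """
    nonempty = int(np.count_nonzero(hist.counts > 0))
    if nonempty < 4:
        raise ValueError(f"need at least 4 non-empty bins to fit, got {nonempty}")
    x = hist.midpoints
    y = hist.counts
    # moment-based start from the count-weighted log diameters
    w = np.maximum(y, 0.0)
    logs = np.log(np.maximum(x, 1e-9))
    mu0 = float(np.average(logs, weights=w))
    sigma0 = float(np.sqrt(max(np.average((logs - mu0) ** 2, weights=w), 1e-4)))
    width = float(np.mean(np.diff(hist.bin_edges)))
    scale0 = float(y.sum() * width)

    def model(xv, mu, sigma, scale):
        return scale * lognorm.pdf(xv, s=sigma, scale=np.exp(mu))

    # bounds keep the distribution anchored to the observed diameter range:
    # without them the far tail of an arbitrarily displaced, arbitrarily
    # broad LogNormal can mimic any slowly varying curve
    lo = (np.log(x[0] / 4.0), 5e-2, 0.0)
    hi = (np.log(x[-1] * 2.0), 3.0, np.inf)
    try:
        popt, _ = curve_fit(
            model, x, y,
            p0=(np.clip(mu0, lo[0], hi[0]), np.clip(sigma0, lo[1], hi[1]), scale0),
            bounds=(lo, hi), maxfev=20_000,
        )
    except RuntimeError as exc:  # pragma: no cover - hard to trigger deterministically
        raise FitConvergenceError(f"LogNormal fit did not converge: {exc}") from exc
    mu, sigma, scale = float(popt[0]), float(popt[1]), float(popt[2])
    resid = y - model(x, mu, sigma, scale)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:  # constant counts carry no variance to explain
        r2 = 1.0 if ss_res <= 1e-20 * float(np.sum(y**2)) else 0.0
    return LogNormalFit(mu=mu, sigma=sigma, scale=scale, r_squared=r2)


def density(mass_g: float, volume_cm3: float) -> float:
    """Density ``rho = m / V`` in g/cm^3."""
    if volume_cm3 <= 0:
        raise ValueError(f"volume must be positive, got {volume_cm3}")
    return mass_g / volume_cm3


def elastic_modulus(stress_kpa: float, strain: float) -> float:
    """Young's modulus ``E = sigma / epsilon`` in kPa."""
    if strain <= 0:
        raise ValueError(f"strain must be positive, got {strain}")
    return stress_kpa / strain


def pva_weight(concentration_pct: float, water_volume_ml: float) -> float:
    """PVA powder weight for a target concentration in a water volume.

    Computed as ``concentration * volume / 100``; with 7% and 150 mL this
    gives 10.5, the worked recipe value.  (The value is reported in the
    recipe's printed unit, mg, although dimensional analysis of percent
    times millilitres would give grams; the number, not the unit, is what
    the recipe fixes.)
    """
    if concentration_pct < 0 or water_volume_ml <= 0:
        raise ValueError("concentration must be >= 0 and volume > 0")
    return concentration_pct * water_volume_ml / 100.0


def read_pore_diameters(path) -> np.ndarray:
    """Read a single-column CSV of pore diameters in micrometres."""
    df = pd.read_csv(path, header=None, comment="#")
    col = df.iloc[:, 0]
    if col.dtype == object:  # header row present
        df = pd.read_csv(path, comment="#")
        col = df.iloc[:, 0]
    return col.to_numpy(dtype=float)


def write_histogram_summary(hist: PoreHistogram, fit: Optional[LogNormalFit], csv_path, json_path=None):
    """Write histogram (CSV) and fit parameters (JSON) to disk."""
    df = pd.DataFrame({
        "bin_lo_um": hist.bin_edges[:-1],
        "bin_hi_um": hist.bin_edges[1:],
        "count": hist.counts,
    })
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        payload = {
            "n_pores": hist.total,
            "n_out_of_range": hist.n_out_of_range,
            "n_samples_averaged": hist.n_samples_averaged,
        }
        if fit is not None:
            payload["lognormal"] = {
                "mu": fit.mu, "sigma": fit.sigma, "scale": fit.scale,
                "r_squared": fit.r_squared, "median_diameter_um": fit.median_diameter,
            }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2)
    return df
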