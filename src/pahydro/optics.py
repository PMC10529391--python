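"""Integrating-sphere optics and inverse Monte-Carlo property estimation.

Integrating-sphere power readings are reduced to three observables: the
directional-diffuse reflectance ``Rcd = m * Pr / Pd``, the
directional-diffuse transmittance ``Tcd = m * Pt / Pd`` and the coherent
(unscattered) transmittance ``Tc = Pcoh / Po``, with ``m`` the sphere-wall
reflection coefficient.  A photon random walk through a homogeneous,
index-matched slab with Henyey-Greenstein scattering serves as the forward
model, and a downhill-simplex (Nelder-Mead) search inverts the measured
triplet for the absorption coefficient ``mu_a``, scattering coefficient
``mu_s`` and anisotropy ``g``.

The forward model is deliberately minimal: no sphere-exchange corrections,
no specular port, single homogeneous layer, boundaries index-matched by
default.  It is this package's own documented stand-in for a full
integrating-sphere radiative-transfer treatment, adequate for the thin
(~100 um) hydrogel films it is applied to.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "SphereMeasurement",
    "OpticalProperties",
    "MCResult",
    "InversionConfig",
    "InversionResult",
    "reflectance_cd",
    "transmittance_cd",
    "transmittance_coherent",
    "reduced_scattering",
    "mc_forward_slab",
    "invert_optical_props",
    "read_sphere_measurements",
    "write_optical_results",
]


@dataclass(frozen=True)
class SphereMeasurement:
    """Raw detector powers from the integrating-sphere setup.

    Powers are in consistent arbitrary units: ``Pd`` (diffuse-diffuse
    reference), ``Pr`` (reflection, collimated illumination), ``Pt``
    (transmission), ``Pcoh`` (unscattered transmitted light) and ``Po``
    (incident).  ``m_wall`` is the sphere wall reflection coefficient and
    ``thickness_um`` the slab thickness in micrometres.
    """

    Pd: float
    Pr: float
    Pt: float
    Pcoh: float
    Po: float
    m_wall: float = 0.98
    thickness_um: float = 100.0

    def __post_init__(self) -> None:
        for name in ("Pd", "Pr", "Pt", "Pcoh", "Po"):
            if getattr(self, name) < 0:
                raise ValueError(f"power {name} must be non-negative")
        if not 0 < self.m_wall <= 1:
            raise ValueError(f"wall reflection coefficient must be in (0, 1], got {self.m_wall}")
        if self.thickness_um <= 0:
            raise ValueError(f"thickness must be positive, got {self.thickness_um}")

    def scaled(self, k: float) -> "SphereMeasurement":
        """All powers multiplied by ``k`` (the observables are scale-free)."""
        return SphereMeasurement(
            self.Pd * k, self.Pr * k, self.Pt * k, self.Pcoh * k, self.Po * k,
            self.m_wall, self.thickness_um,
        )


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of a slab sample (coefficients in cm^-1)."""

    mu_a: float
    mu_s: float
    g: float

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("absorption and scattering coefficients must be non-negative")
        if not -1.0 < self.g < 1.0:
            raise ValueError(f"anisotropy must satisfy -1 < g < 1, got {self.g}")

    @property
    def mu_s_prime(self) -> float:
        """Reduced scattering coefficient ``mu_s * (1 - g)`` in cm^-1."""
        return self.mu_s * (1.0 - self.g)

    @property
    def mu_t(self) -> float:
        return self.mu_a + self.mu_s


def reflectance_cd(meas: SphereMeasurement) -> float:
    """Directional-diffuse reflectance ``Rcd = m * Pr / Pd``."""
    if meas.Pd == 0:
        raise ZeroDivisionError("reference power Pd is zero")
    return meas.m_wall * meas.Pr / meas.Pd


def transmittance_cd(meas: SphereMeasurement) -> float:
    """Directional-diffuse transmittance ``Tcd = m * Pt / Pd``."""
    if meas.Pd == 0:
        raise ZeroDivisionError("reference power Pd is zero")
    return meas.m_wall * meas.Pt / meas.Pd


def transmittance_coherent(meas: SphereMeasurement) -> float:
    """Coherent transmittance ``Tc = Pcoh / Po``."""
    if meas.Po == 0:
        raise ZeroDivisionError("incident power Po is zero")
    return meas.Pcoh / meas.Po


def reduced_scattering(mu_s: float, g: float) -> float:
    """Reduced scattering coefficient ``mu_s' = mu_s * (1 - g)``."""
    return mu_s * (1.0 - g)


class MCResult(NamedTuple):
    """Photon-fraction tallies of one forward Monte-Carlo run."""

    r_diffuse: float
    t_diffuse: float
    t_coherent: float
    absorbed: float
    n_photons: int

    @property
    def total(self) -> float:
        return self.r_diffuse + self.t_diffuse + self.t_coherent + self.absorbed


def _hg_cosine(g: float, u: np.ndarray) -> np.ndarray:
    """Sample scattering-angle cosines from the Henyey-Greenstein phase
    function via its inverse CDF; isotropic when g == 0."""
    if abs(g) < 1e-12:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return (1.0 + g * g - tmp * tmp) / (2.0 * g)


def _fresnel_reflectance(n_rel: float, cos_i: np.ndarray) -> np.ndarray:
    """Unpolarized Fresnel reflectance for incidence cosines ``cos_i``
    going from the slab (index ``n_rel``) into the surround (index 1)."""
    cos_i = np.clip(cos_i, 0.0, 1.0)
    sin_t2 = (n_rel * np.sqrt(np.maximum(0.0, 1.0 - cos_i**2))) ** 2
    R = np.ones_like(cos_i)  # total internal reflection by default
    ok = sin_t2 < 1.0
    cos_t = np.sqrt(1.0 - sin_t2[ok])
    ci = cos_i[ok]
    rs = (n_rel * ci - cos_t) / (n_rel * ci + cos_t)
    rp = (ci - n_rel * cos_t) / (ci + n_rel * cos_t)
    R[ok] = 0.5 * (rs**2 + rp**2)
    return R


def mc_forward_slab(
    props: OpticalProperties,
    thickness_um: float,
    n_photons: int = 100_000,
    seed: Optional[int] = None,
    max_events: int = 400,
    weight_cutoff: float = 1e-4,
    n_rel: float = 1.0,
) -> MCResult:
    """Weighted photon random walk through a homogeneous, index-matched slab.

    Photons of unit weight enter at ``z = 0`` travelling along +z.  Free
    paths are sampled from ``exp(-mu_t * s)``; at each interaction a
    fraction ``mu_a / mu_t`` of the photon's weight is deposited as
    absorbed and the survivor scatters into a new direction drawn from the
    Henyey-Greenstein phase function (absorption weighting, which makes
    the tallies vary smoothly with ``mu_a``).  Weight leaving through
    ``z = d`` without any scattering event is tallied as coherent
    transmittance (converging to the Beer-Lambert value
    ``exp(-mu_t * d)``); scattered weight leaving forward/backward is the
    diffuse transmittance/reflectance.  Residual weight of photons that
    fall below ``weight_cutoff`` (or exceed ``max_events``) is deposited
    as absorbed, so the four tallies sum to one exactly.

    Boundaries are index-matched by default (``n_rel = 1``).  With
    ``n_rel > 1`` (slab denser than the surround) an unpolarized Fresnel
    reflection is applied at each boundary crossing, including total
    internal reflection beyond the critical angle; the entry face is
    still treated as matched for the incoming collimated beam.

    Random numbers are assigned per photon *slot* and event, so two runs
    with the same ``seed`` but different optical properties reuse the same
    underlying uniforms: the tallies are then a smooth function of the
    properties (common random numbers), which the downhill-simplex
    inversion relies on.
    """
    if n_photons < 1000:
        raise ValueError(f"need at least 1000 photons, got {n_photons}")
    d = thickness_um * 1e-4  # um -> cm
    rng = np.random.default_rng(seed)
    mu_t = props.mu_t
    if mu_t == 0.0:
        return MCResult(0.0, 0.0, 1.0, 0.0, n_photons)
    albedo = props.mu_s / mu_t

    n = int(n_photons)
    z = np.zeros(n)
    ux = np.zeros(n)
    uy = np.zeros(n)
    uz = np.ones(n)
    w = np.ones(n)
    scattered = np.zeros(n, dtype=bool)
    alive = np.ones(n, dtype=bool)
    w_r = w_td = w_tc = w_abs = 0.0

    for _ in range(max_events):
        if not np.any(alive):
            break
        # draw for every slot (not just the alive ones) so that photon k at
        # event e always consumes the same uniforms, whatever the parameters
        u_step = rng.random(n)
        u_scat = rng.random(n)
        u_phi = rng.random(n)

        idx = np.nonzero(alive)[0]
        step = -np.log(u_step[idx]) / mu_t
        z_c = z[idx] + uz[idx] * step
        uz_c = uz[idx].copy()
        w_c = w[idx].copy()
        sc_c = scattered[idx]
        # fold the free path at the slab faces: the transmitted weight
        # fraction (all of it for matched boundaries) is tallied, the
        # Fresnel-reflected remainder continues along the mirrored path
        for _bounce in range(50):
            out_top = z_c >= d
            out_bot = z_c <= 0.0
            out = out_top | out_bot
            if not np.any(out):
                break
            if n_rel == 1.0:
                R = np.zeros(int(np.count_nonzero(out)))
            else:
                R = _fresnel_reflectance(n_rel, np.abs(uz_c[out]))
            w_exit = w_c[out] * (1.0 - R)
            top = out_top[out]
            sc = sc_c[out]
            w_tc += float(w_exit[top & ~sc].sum())
            w_td += float(w_exit[top & sc].sum())
            w_r += float(w_exit[~top].sum())
            w_c[out] *= R
            z_fold = z_c.copy()
            z_fold[out_top] = 2.0 * d - z_c[out_top]
            z_fold[out_bot] = -z_c[out_bot]
            z_c = z_fold
            uz_c[out] = -uz_c[out]
            if n_rel == 1.0:
                break  # no reflected weight to fold further
        z[idx] = np.clip(z_c, 0.0, d)
        uz[idx] = uz_c
        w[idx] = w_c
        dead = w_c < weight_cutoff
        w_abs += float(w_c[dead].sum())  # exactly zero for matched exits
        alive[idx[dead]] = False
        inside = idx[~dead]
        if inside.size == 0:
            continue
        # deposit the absorbed fraction of the weight, keep the survivor
        w_abs += float(w[inside].sum()) * (1.0 - albedo)
        w[inside] *= albedo
        low = w[inside] < weight_cutoff
        if np.any(low):
            dead = inside[low]
            w_abs += float(w[dead].sum())
            alive[dead] = False
            inside = inside[~low]
            if inside.size == 0:
                continue
        # Henyey-Greenstein deflection with uniform azimuth
        ct = _hg_cosine(props.g, u_scat[inside])
        st = np.sqrt(np.maximum(0.0, 1.0 - ct * ct))
        phi = 2.0 * np.pi * u_phi[inside]
        cp, sp = np.cos(phi), np.sin(phi)
        uxs, uys, uzs = ux[inside], uy[inside], uz[inside]
        near_vertical = np.abs(uzs) > 0.99999
        denom = np.sqrt(np.maximum(1e-30, 1.0 - uzs * uzs))
        nx = st * (uxs * uzs * cp - uys * sp) / denom + uxs * ct
        ny = st * (uys * uzs * cp + uxs * sp) / denom + uys * ct
        nz = -st * cp * denom + uzs * ct
        nx = np.where(near_vertical, st * cp, nx)
        ny = np.where(near_vertical, st * sp, ny)
        nz = np.where(near_vertical, np.sign(uzs) * ct, nz)
        norm = np.sqrt(nx * nx + ny * ny + nz * nz)
        ux[inside], uy[inside], uz[inside] = nx / norm, ny / norm, nz / norm
        scattered[inside] = True

    # photons still alive after max_events (vanishingly rare) -> absorbed
    w_abs += float(w[alive].sum())
    return MCResult(w_r / n, w_td / n, w_tc / n, w_abs / n, n)


@dataclass
class InversionConfig:
    """Settings of the downhill-simplex inverse Monte-Carlo search."""

    n_photons: int = 100_000
    seed: int = 0
    x0: tuple = (0.5, 20.0, 0.7)  # (mu_a cm^-1, mu_s cm^-1, g) start
    max_iter: int = 400
    tol: float = 1e-4  # simplex spread in log-parameter space
    fix_g: Optional[float] = None
    fix_mu_s: Optional[float] = None


@dataclass
class InversionResult:
    """Best-fit optical properties with diagnostics."""

    props: OpticalProperties
    residual: float
    converged: bool
    n_evaluations: int = 0
    diverging_absorption: bool = False


_GMAX = 0.999


def invert_optical_props(
    r_cd: float,
    t_cd: float,
    t_c: float,
    thickness_um: float,
    config: Optional[InversionConfig] = None,
) -> InversionResult:
    """Estimate ``(mu_a, mu_s, g)`` from a measured (Rcd, Tcd, Tc) triplet.

    A Nelder-Mead simplex minimises the sum of squared residuals between
    the forward Monte-Carlo observables and the measured triplet.  The
    Monte-Carlo engine is re-seeded identically at every evaluation
    (common random numbers), so the objective is deterministic and the
    search reproducible.

    ``config.fix_g`` pins the anisotropy (useful when ``Tc`` is negligible
    and only two informative observables remain); ``config.fix_mu_s = 0``
    switches to the closed-form Beer-Lambert inverse
    ``mu_a = -ln(Tc) / d``.

    A measured triplet that is zero in all components is flagged as
    diverging absorption (an effectively opaque sample) rather than fitted.
    """
    cfg = config or InversionConfig()
    for name, v in (("Rcd", r_cd), ("Tcd", t_cd), ("Tc", t_c)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if thickness_um <= 0:
        raise ValueError("thickness must be positive")
    d_cm = thickness_um * 1e-4

    if r_cd == 0.0 and t_cd == 0.0 and t_c == 0.0:
        return InversionResult(
            props=OpticalProperties(mu_a=np.inf, mu_s=0.0, g=0.0),
            residual=np.nan,
            converged=False,
            diverging_absorption=True,
        )

    if cfg.fix_mu_s is not None and cfg.fix_mu_s == 0.0:
        if t_c <= 0:
            raise ValueError("Tc must be positive for the pure-absorption inverse")
        mu_a = -np.log(t_c) / d_cm
        props = OpticalProperties(mu_a=mu_a, mu_s=0.0, g=cfg.fix_g or 0.0)
        return InversionResult(props=props, residual=0.0, converged=True, n_evaluations=0)

    target = np.array([r_cd, t_cd, t_c])

    def unpack(p: np.ndarray) -> OpticalProperties:
        mu_a = np.exp(p[0])
        mu_s = cfg.fix_mu_s if cfg.fix_mu_s is not None else np.exp(p[1])
        if cfg.fix_g is not None:
            g = cfg.fix_g
        else:
            g = _GMAX * np.tanh(p[-1])
        return OpticalProperties(mu_a=mu_a, mu_s=mu_s, g=g)

    n_eval = 0

    def objective(p: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        props = unpack(p)
        sim = mc_forward_slab(props, thickness_um, cfg.n_photons, seed=cfg.seed)
        model = np.array([sim.r_diffuse, sim.t_diffuse, sim.t_coherent])
        return float(np.sum((model - target) ** 2))

    mu_a0, mu_s0, g0 = cfg.x0
    p0 = [np.log(max(mu_a0, 1e-6))]
    if cfg.fix_mu_s is None:
        p0.append(np.log(max(mu_s0, 1e-6)))
    if cfg.fix_g is None:
        p0.append(np.arctanh(np.clip(g0, -0.99, 0.99) / _GMAX))
    res = minimize(
        objective,
        np.array(p0),
        method="Nelder-Mead",
        options={"maxiter": cfg.max_iter, "fatol": 1e-12, "xatol": cfg.tol},
    )
    return InversionResult(
        props=unpack(res.x),
        residual=float(res.fun),
        converged=bool(res.success),
        n_evaluations=n_eval,
    )


def read_sphere_measurements(path) -> "dict[str, SphereMeasurement]":
    """Read integrating-sphere power readings from a CSV table.

    Expected columns: ``sample_id, Pd, Pr, Pt, Pcoh, Po, thickness_um``
    (optional ``m_wall``).  Returns a mapping from sample id to
    :class:`SphereMeasurement`.
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"sample_id", "Pd", "Pr", "Pt", "Pcoh", "Po", "thickness_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns in {path}: {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        kwargs = dict(
            Pd=row["Pd"], Pr=row["Pr"], Pt=row["Pt"], Pcoh=row["Pcoh"], Po=row["Po"],
            thickness_um=row["thickness_um"],
        )
        if "m_wall" in df.columns:
            kwargs["m_wall"] = row["m_wall"]
        out[str(row["sample_id"])] = SphereMeasurement(**kwargs)
    return out


def write_optical_results(results: "dict[str, OpticalProperties]", path):
    """Write per-sample optical properties as a CSV with columns
    ``sample_id, mu_a_cm1, mu_s_cm1, mu_s_prime_cm1, g``."""
    import pandas as pd

    rows = [
        {
            "sample_id": sid,
            "mu_a_cm1": p.mu_a,
            "mu_s_cm1": p.mu_s,
            "mu_s_prime_cm1": p.mu_s_prime,
            "g": p.g,
        }
        for sid, p in results.items()
    ]
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
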