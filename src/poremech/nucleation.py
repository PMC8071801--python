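"""Continuum nucleation model of membrane rupture under an AFM tip.

The model treats failure of a supported lipid bilayer under a loaded
cantilever tip as thermally activated nucleation of a circular hole.
A hole of radius ``r_h`` costs rim (line-tension) energy and releases
surface and mechanical energy::

    U(r_h) = 2 pi r_h Gamma + pi r_h^2 (S - F / (2 pi R))

with line tension ``Gamma`` (N), spreading pressure ``S`` (N/m), tip
radius ``R`` (m) and applied force ``F`` (N).  Once the force exceeds
the spreading force ``F0 = 2 pi R S``, U passes through a maximum at
the critical radius ``r_c = 2 pi R Gamma / (F - F0)`` with barrier
height ``dU = 2 pi^2 Gamma^2 R / (F - F0)``.

Under a constant loading rate ``dF/dt = K nu`` (cantilever stiffness
times approach velocity) and an attempt frequency ``A``, rupture is a
first-passage process with force-dependent hazard

    h(F) = (A / (K nu)) * exp(-dU(F) / kT)        [per unit force]

so the survival probability and yield-force density are

    s(F) = exp(-Int_{F0}^{F} h(F') dF'),   p(F) = h(F) * s(F).

The inner integral has the closed form (u = F - F0, c = 2 pi^2 Gamma^2
R / kT)::

    I(u) = Int_0^u exp(-c/u') du' = u exp(-c/u) + c Ei(-c/u)

with Ei the exponential integral.  Fitting p(F) to a population of
measured yield forces recovers (Gamma, S); all other parameters are
fixed by the experiment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, special

from .constants import KB_J

__all__ = [
    "NucleationParams",
    "FitResult",
    "hole_energy",
    "critical_radius",
    "barrier",
    "survival",
    "pdf",
    "log_pdf",
    "cdf",
    "sample_forces",
    "fit",
    "bootstrap_ci",
]


@dataclass(frozen=True)
class NucleationParams:
    """Physical parameter set of the nucleation model (SI units).

    Attributes
    ----------
    gamma : line tension of the hole rim (N).
    spreading_pressure : spreading pressure S (N/m); the net interfacial
        free-energy change per area of removing a membrane patch between
        tip and substrate.  Sets the threshold force ``2 pi R S``.
    tip_radius : cantilever tip radius R (m).
    spring_constant : cantilever spring constant K (N/m).
    velocity : approach velocity nu (m/s).
    attempt_frequency : attempt frequency A (1/s), bounded above by the
        cantilever resonance frequency.
    temperature : absolute temperature (K).
    """

    gamma: float
    spreading_pressure: float
    tip_radius: float = 20e-9
    spring_constant: float = 0.060
    velocity: float = 1e-6
    attempt_frequency: float = 3000.0
    temperature: float = 298.0

    def __post_init__(self):
        for name in (
            "gamma",
            "spreading_pressure",
            "tip_radius",
            "spring_constant",
            "velocity",
            "attempt_frequency",
            "temperature",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"NucleationParams.{name} must be positive and finite, got {v!r}")

    @property
    def threshold_force(self) -> float:
        """Spreading force ``2 pi R S`` (N) below which no barrier exists."""
        return 2.0 * np.pi * self.tip_radius * self.spreading_pressure

    @property
    def loading_rate(self) -> float:
        """Loading rate ``K nu`` (N/s)."""
        return self.spring_constant * self.velocity

    @property
    def kT(self) -> float:
        """Thermal energy (J)."""
        return KB_J * self.temperature


@dataclass
class FitResult:
    """Outcome of a (Gamma, S) fit.

    Estimates and standard errors are SI (N and N/m).  ``objective`` is
    the maximized log-likelihood (``method='mle'``) or the negative
    residual sum of squares (``method='histogram'``).
    """

    gamma: float
    spreading_pressure: float
    gamma_se: float
    spreading_pressure_se: float
    objective: float
    method: str
    converged: bool
    n: int
    params: NucleationParams = None
    message: str = ""

    def as_paper_units(self) -> dict:
        """Estimates in the conventional reporting units.

        Gamma in 1e-3 nN (= pN) and S in 1e-3 N/m (= mN/m).
        """
        return {
            "gamma_1e-3_nN": self.gamma / 1e-12,
            "gamma_se_1e-3_nN": self.gamma_se / 1e-12,
            "S_1e-3_N_per_m": self.spreading_pressure / 1e-3,
            "S_se_1e-3_N_per_m": self.spreading_pressure_se / 1e-3,
        }


def hole_energy(r_h, force, params: NucleationParams):
    """Energy U (J) of a circular hole of radius ``r_h`` (m) at force ``force`` (N)."""
    r_h = np.asarray(r_h, dtype=float)
    return (
        2.0 * np.pi * r_h * params.gamma
        + np.pi * r_h**2
        * (params.spreading_pressure - force / (2.0 * np.pi * params.tip_radius))
    )


def critical_radius(force, params: NucleationParams):
    """Radius (m) at which the hole energy is maximal; requires ``force > 2 pi R S``."""
    f0 = params.threshold_force
    force = np.asarray(force, dtype=float)
    if np.any(force <= f0):
        raise ValueError(
            f"force must exceed the spreading force 2*pi*R*S = {f0:.4g} N; "
            "below it the hole energy has no barrier"
        )
    return 2.0 * np.pi * params.tip_radius * params.gamma / (force - f0)


def barrier(force, params: NucleationParams):
    """Activation barrier dU(F) = 2 pi^2 Gamma^2 R / (F - 2 pi R S), in J."""
    f0 = params.threshold_force
    force = np.asarray(force, dtype=float)
    if np.any(force <= f0):
        raise ValueError(
            f"force must exceed the spreading force 2*pi*R*S = {f0:.4g} N"
        )
    return 2.0 * np.pi**2 * params.gamma**2 * params.tip_radius / (force - f0)


def _barrier_scale(params: NucleationParams) -> float:
    """c = 2 pi^2 Gamma^2 R / kT, the barrier scale expressed as a force (N)."""
    return 2.0 * np.pi**2 * params.gamma**2 * params.tip_radius / params.kT


def _hazard_integral(u, c):
    """Closed form of Int_0^u exp(-c/u') du' for u >= 0 (all quantities in N).

    Equals ``u*exp(-c/u) + c*Ei(-c/u)``; evaluates to 0 at u = 0.
    """
    u = np.asarray(u, dtype=float)
    out = np.zeros_like(u)
    pos = u > 0
    up = u[pos]
    x = c / up
    # expi underflows harmlessly for large x; silence the warning
    with np.errstate(over="ignore", under="ignore"):
        out[pos] = up * np.exp(-x) + c * special.expi(-x)
    return np.clip(out, 0.0, None)


def survival(force, params: NucleationParams):
    """Probability that the membrane has not ruptured by force ``force`` (N)."""
    f0 = params.threshold_force
    a = params.attempt_frequency / params.loading_rate
    c = _barrier_scale(params)
    u = np.clip(np.asarray(force, dtype=float) - f0, 0.0, None)
    return np.exp(-a * _hazard_integral(u, c))


def log_pdf(force, params: NucleationParams):
    """Natural log of the yield-force density; -inf at or below threshold."""
    f0 = params.threshold_force
    a = params.attempt_frequency / params.loading_rate
    c = _barrier_scale(params)
    force = np.asarray(force, dtype=float)
    u = force - f0
    out = np.full(np.shape(u), -np.inf, dtype=float)
    pos = u > 0
    up = np.atleast_1d(u)[np.atleast_1d(pos)]
    val = np.log(a) - c / up - a * _hazard_integral(up, c)
    if np.isscalar(force) or force.ndim == 0:
        return float(val[0]) if pos else -np.inf
    out[pos] = val
    return out


def pdf(force, params: NucleationParams):
    """Yield-force probability density (1/N); zero at or below 2 pi R S."""
    return np.exp(log_pdf(force, params))


def cdf(force, params: NucleationParams):
    """P(yield force <= F) = 1 - survival(F)."""
    return 1.0 - survival(force, params)


def _inverse_hazard_integral(targets, c):
    """Solve I(u) = t for u (vectorized), by log-log interpolation + Newton."""
    targets = np.asarray(targets, dtype=float)
    tmax = targets.max()
    # bracket: I(u) <= u, so u_hi >= tmax; expand until I(u_hi) > tmax
    u_hi = max(tmax, c)
    while _hazard_integral(u_hi, c) <= tmax:
        u_hi *= 2.0
    # lower end: smallest target; I(u) ~ u^2/c * exp(-c/u) for small u
    u_lo = c / max(np.log(c / targets.min()) + 2.0, 2.0) if targets.min() < c else targets.min()
    while _hazard_integral(u_lo, c) >= targets.min():
        u_lo *= 0.5
    grid = np.geomspace(u_lo, u_hi, 4096)
    vals = _hazard_integral(grid, c)
    u = np.interp(np.log(targets), np.log(np.clip(vals, 1e-300, None)), np.log(grid))
    u = np.exp(u)
    # Newton polish in log-space: d I / d ln u = u exp(-c/u)
    for _ in range(3):
        res = _hazard_integral(u, c) - targets
        with np.errstate(over="ignore", under="ignore"):
            deriv = u * np.exp(-c / u)
        step = np.where(deriv > 0, res / np.clip(deriv, 1e-300, None), 0.0)
        u = u * np.exp(-np.clip(step, -1.0, 1.0))
    return u


def sample_forces(params: NucleationParams, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` yield forces (N) from the nucleation-model density.

    Uses exact inverse-CDF sampling: with a ~ A/(K nu), the CDF is
    ``1 - exp(-a I(F - F0))``, so ``F = F0 + I^{-1}(-ln(1-p)/a)``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    a = params.attempt_frequency / params.loading_rate
    c = _barrier_scale(params)
    p = rng.uniform(size=n)
    targets = -np.log1p(-p) / a
    u = _inverse_hazard_integral(targets, c)
    return params.threshold_force + u


def _negloglik(theta, forces, fixed: NucleationParams):
    """Negative log-likelihood; theta = (Gamma in pN, S in mN/m)."""
    gamma = theta[0] * 1e-12
    s = theta[1] * 1e-3
    if gamma <= 0 or s <= 0:
        return 1e12
    f0 = 2.0 * np.pi * fixed.tip_radius * s
    fmin = forces.min()
    if f0 >= fmin:
        # smooth penalty pushing the threshold back below the data
        return 1e6 * (1.0 + (f0 - fmin) / fmin) ** 2
    p = replace(fixed, gamma=gamma, spreading_pressure=s)
    ll = log_pdf(forces, p)
    return -float(np.sum(ll))


def _hessian_fd(fun, x, rel_step=1e-4):
    """Central finite-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    k = len(x)
    h = rel_step * np.maximum(np.abs(x), 1e-8)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def _default_init(forces, fixed: NucleationParams):
    """Heuristic starting point: threshold just below the data minimum,
    line tension matched to the spread of the distribution."""
    fmin = float(forces.min())
    s0 = 0.85 * fmin / (2.0 * np.pi * fixed.tip_radius)
    # barrier scale c controls the width: median - min ~ c / log-ish factor
    c0 = max(float(np.median(forces) - 0.85 * fmin), 0.1 * fmin)
    gamma0 = np.sqrt(c0 * fixed.kT / (2.0 * np.pi**2 * fixed.tip_radius))
    return gamma0, s0


def fit(
    forces,
    fixed: NucleationParams | None = None,
    init: tuple[float, float] | None = None,
    method: str = "mle",
    **fixed_kwargs,
) -> FitResult:
    """Fit (Gamma, S) to a population of yield forces (N).

    Parameters
    ----------
    forces : array of yield forces in N.
    fixed : NucleationParams carrying the fixed experimental parameters
        (R, K, nu, A, T); its gamma/S entries are ignored as such and only
        used as the starting point when `init` is None and they are sane.
    init : optional (Gamma0, S0) in SI units.
    method : 'mle' (default) maximizes the exact log-likelihood;
        'histogram' least-squares fits the density to a normalized
        histogram with Freedman-Diaconis binning.
    """
    forces = np.asarray(forces, dtype=float)
    if forces.ndim != 1 or len(forces) < 5:
        raise ValueError("need a 1-d array of at least 5 yield forces")
    if np.any(forces <= 0):
        raise ValueError("yield forces must be positive")
    if len(forces) < 100:
        warnings.warn("fewer than 100 forces: estimates will be noisy", stacklevel=2)
    if fixed is None:
        fixed = NucleationParams(gamma=1e-12, spreading_pressure=1e-3, **fixed_kwargs)

    if init is None:
        gamma0, s0 = _default_init(forces, fixed)
    else:
        gamma0, s0 = init
    x0 = np.array([gamma0 / 1e-12, s0 / 1e-3])
    s_max = 0.999 * forces.min() / (2.0 * np.pi * fixed.tip_radius) / 1e-3
    bounds = [(1e-4, None), (1e-6, s_max)]

    if method == "mle":
        obj = lambda th: _negloglik(th, forces, fixed)
    elif method == "histogram":
        counts, edges = np.histogram(forces, bins="fd", density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])

        def obj(th):
            gamma = th[0] * 1e-12
            s = th[1] * 1e-3
            if gamma <= 0 or s <= 0:
                return 1e12
            p = replace(fixed, gamma=gamma, spreading_pressure=s)
            dens = pdf(centers, p)
            return float(np.sum((dens - counts) ** 2)) * 1e-18  # (1/N)^2 -> (1/nN)^2

    else:
        raise ValueError(f"unknown fit method {method!r}")

    if init is None:
        res = optimize.minimize(
            obj, x0, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 4000},
        )
        x_start = res.x
    else:
        # trusted starting point (e.g. bootstrap refits): skip the
        # derivative-free global stage
        res = None
        x_start = x0
    res2 = optimize.minimize(obj, x_start, method="L-BFGS-B", bounds=bounds)
    best = res2 if res is None or res2.fun <= res.fun else res

    gamma_hat = best.x[0] * 1e-12
    s_hat = best.x[1] * 1e-3
    gamma_se = s_se = np.nan
    if method == "mle":
        try:
            H = _hessian_fd(obj, best.x)
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            if np.all(d > 0):
                gamma_se = np.sqrt(d[0]) * 1e-12
                s_se = np.sqrt(d[1]) * 1e-3
        except np.linalg.LinAlgError:
            pass
    out_params = replace(fixed, gamma=gamma_hat, spreading_pressure=s_hat)
    return FitResult(
        gamma=gamma_hat,
        spreading_pressure=s_hat,
        gamma_se=float(gamma_se) if np.isfinite(gamma_se) else 0.0,
        spreading_pressure_se=float(s_se) if np.isfinite(s_se) else 0.0,
        objective=-best.fun,
        method=method,
        converged=bool(best.success or res.success),
        n=len(forces),
        params=out_params,
        message=str(best.message),
    )


def bootstrap_ci(
    forces,
    fixed: NucleationParams,
    n_boot: int = 200,
    seed=None,
    level: float = 0.95,
    method: str = "mle",
):
    """Percentile bootstrap confidence intervals for (Gamma, S).

    Case-resamples the force sample, refits each replicate starting from
    the full-sample estimate, and returns a dict with the point
    estimates, the (lo, hi) intervals (SI units) and the number of
    failed refits.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if n_boot == 1:
        warnings.warn("n_boot=1 yields a degenerate interval", stacklevel=2)
    forces = np.asarray(forces, dtype=float)
    rng = np.random.default_rng(seed)
    full = fit(forces, fixed, method=method)
    gammas, ss = [], []
    failures = 0
    for _ in range(n_boot):
        resampled = rng.choice(forces, size=len(forces), replace=True)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = fit(resampled, fixed, init=(full.gamma, full.spreading_pressure), method=method)
            if not r.converged:
                failures += 1
                continue
            gammas.append(r.gamma)
            ss.append(r.spreading_pressure)
        except (ValueError, FloatingPointError):
            failures += 1
    alpha = 0.5 * (1.0 - level)
    qs = [100 * alpha, 100 * (1 - alpha)]
    return {
        "gamma": full.gamma,
        "spreading_pressure": full.spreading_pressure,
        "gamma_ci": tuple(np.percentile(gammas, qs)) if gammas else (np.nan, np.nan),
        "spreading_pressure_ci": tuple(np.percentile(ss, qs)) if ss else (np.nan, np.nan),
        "n_boot": n_boot,
        "failures": failures,
    }
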