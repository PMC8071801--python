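"""Potential-of-mean-force toolkit: WHAM, Bayesian bootstrap errors,
pore free energies, and area scaling to experimental membranes.

Umbrella-sampling time series of the chain coordinate ``xi`` (one
harmonic window per restraint position) are combined into an unbiased
free-energy profile G(xi) with the weighted histogram analysis method.
The pore free energy ``dG_pore`` is the plateau of G at large xi (open
pore) minus its minimum near the flat-membrane state.  Because the
probability of spontaneously finding a pore is proportional to membrane
area, a simulation-box value translates to a membrane of area A_exp as

    dG_exp = dG_pore - kT ln(A_exp / A_sim)

and the open-pore probability follows the two-state occupancy
``1 / (1 + exp(dG / kT))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .constants import kT_kJmol

__all__ = [
    "Window",
    "UmbrellaDataset",
    "PMF",
    "wham",
    "bayesian_bootstrap_pmf",
    "pore_free_energy",
    "area_scaled_dg",
    "pore_probability",
    "sphere_area",
    "disc_area",
    "read_umbrella_dataset",
    "write_umbrella_dataset",
]


@dataclass
class Window:
    """One umbrella window: harmonic bias ``k/2 (xi - center)^2`` (kJ/mol)."""

    center: float
    force_constant: float
    samples: np.ndarray

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.force_constant <= 0:
            raise ValueError("force constant must be positive")


@dataclass
class UmbrellaDataset:
    """Umbrella-sampling input to WHAM.

    ``equilibration_fraction`` of each window's series is discarded from
    the front before analysis (burn-in), mirroring the usual practice of
    omitting the first part of each window for equilibration.
    """

    windows: list[Window]
    temperature: float = 323.0
    equilibration_fraction: float = 0.5

    def production_samples(self) -> list[np.ndarray]:
        out = []
        for w in self.windows:
            n0 = int(len(w.samples) * self.equilibration_fraction)
            s = w.samples[n0:]
            if len(s) == 0:
                raise ValueError(
                    f"window at center {w.center} is empty after discarding "
                    f"{self.equilibration_fraction:.0%} for equilibration"
                )
            out.append(s)
        return out


@dataclass
class PMF:
    """Free-energy profile G(xi) in kJ/mol, zeroed at its minimum."""

    grid: np.ndarray
    G: np.ndarray
    err: np.ndarray = None
    temperature: float = 323.0

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.err is None:
            self.err = np.zeros_like(self.G)
        else:
            self.err = np.asarray(self.err, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"xi": self.grid, "G_kJ_mol": self.G, "err_kJ_mol": self.err})


def _histograms(dataset: UmbrellaDataset, n_bins: int, xi_range=(0.0, 1.0)):
    edges = np.linspace(xi_range[0], xi_range[1], n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.array(
        [np.histogram(s, bins=edges)[0] for s in dataset.production_samples()],
        dtype=float,
    )
    return centers, counts


def _check_overlap(dataset: UmbrellaDataset, counts: np.ndarray):
    """Adjacent windows (by center) must share at least one populated bin."""
    order = np.argsort([w.center for w in dataset.windows])
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((counts[a] > 0) & (counts[b] > 0)):
            ca = dataset.windows[a].center
            cb = dataset.windows[b].center
            raise ValueError(
                f"umbrella windows at centers {ca:.3f} and {cb:.3f} have no "
                "overlapping histogram support; WHAM cannot connect them"
            )


def _solve_wham(centers, counts, biases_kJ, kT, tolerance, max_iter, f_init=None):
    """Solve the WHAM equations for window offsets and bin probabilities.

    counts: (n_windows, n_bins) histogram counts; biases_kJ: (n_windows,
    n_bins) bias energies at bin centers.  Returns (log p per bin,
    dimensionless window free energies f).

    The self-consistent WHAM equations are the stationarity conditions
    of a convex log-likelihood in the window offsets, so the solver
    minimizes that objective directly (L-BFGS with analytic gradient)
    and then polishes with self-consistent iterations until the maximum
    offset change drops below ``tolerance``.
    """
    from scipy.optimize import minimize

    n_win, n_bins = counts.shape
    N = counts.sum(axis=1)
    logN = np.log(N)
    total = counts.sum(axis=0)
    occupied = total > 0
    log_total = np.full(n_bins, -np.inf)
    log_total[occupied] = np.log(total[occupied])
    b = biases_kJ / kT  # dimensionless bias
    M = total[occupied]
    b_occ = b[:, occupied]

    def objective(x):
        f = np.concatenate([[0.0], x])
        z = logN[:, None] + f[:, None] - b_occ  # (win, occ bins)
        log_den = logsumexp(z, axis=0)
        val = -np.dot(N, f) + np.dot(M, log_den)
        # responsibilities for the gradient
        resp = np.exp(z - log_den[None, :])
        grad_full = -N + resp @ M
        return val, grad_full[1:]

    x0 = (
        np.zeros(n_win - 1)
        if f_init is None
        else np.asarray(f_init, dtype=float)[1:] - f_init[0]
    )
    res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "gtol": 1e-9, "ftol": 1e-15})
    f = np.concatenate([[0.0], res.x])
    # self-consistent polish to the requested tolerance
    delta = np.inf
    for _ in range(max_iter):
        log_den = logsumexp(logN[:, None] + f[:, None] - b, axis=0)
        log_p = log_total - log_den
        f_new = -logsumexp(log_p[None, :] - b, axis=1)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tolerance:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge (residual {delta:.3e} > tolerance {tolerance:.3e})"
        )
    log_den = logsumexp(logN[:, None] + f[:, None] - b, axis=0)
    log_p = log_total - log_den
    return log_p, f


def wham(
    dataset: UmbrellaDataset,
    n_bins: int = 200,
    tolerance: float = 1e-8,
    max_iter: int = 100_000,
    xi_range=(0.0, 1.0),
) -> PMF:
    """Estimate the unbiased PMF from umbrella windows by WHAM.

    The self-consistent equations are iterated until the maximum change
    of the (dimensionless) window offsets drops below ``tolerance``.
    The profile is shifted so its minimum is zero; unpopulated bins get
    ``nan``.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    kT = kT_kJmol(dataset.temperature)
    centers, counts = _histograms(dataset, n_bins, xi_range)
    _check_overlap(dataset, counts)
    k = np.array([w.force_constant for w in dataset.windows])
    x0 = np.array([w.center for w in dataset.windows])
    biases = 0.5 * k[:, None] * (centers[None, :] - x0[:, None]) ** 2
    log_p, _ = _solve_wham(centers, counts, biases, kT, tolerance, max_iter)
    with np.errstate(invalid="ignore"):
        G = -kT * log_p
    G = G - np.nanmin(G)
    G[~np.isfinite(G)] = np.nan
    return PMF(grid=centers, G=G, temperature=dataset.temperature)


def bayesian_bootstrap_pmf(
    dataset: UmbrellaDataset,
    rounds: int = 50,
    seed=None,
    n_bins: int = 200,
    tolerance: float = 1e-8,
    max_iter: int = 100_000,
    xi_range=(0.0, 1.0),
    method: str = "samples",
) -> PMF:
    """WHAM with Bayesian-bootstrap error bars.

    Each round reweights the histograms, re-solves WHAM, and zeroes the
    profile at its minimum; the returned PMF carries the pointwise mean
    across rounds as G and the pointwise standard deviation as err.

    method='samples' (default) draws Dirichlet(1, ..., 1) weights over
    the samples of every window, which acts on a histogram as
    independent Gamma(count) weights per bin renormalized to the window
    total — this resamples the within-window counting noise, the
    dominant error source when each window is a single series of
    independent draws.  method='histograms' draws one Dirichlet weight
    per whole window, the classic scheme for data made of several
    complete histograms per state; it only captures between-window
    disagreement.
    """
    if rounds < 2:
        raise ValueError("need at least 2 bootstrap rounds")
    if method not in ("samples", "histograms", "trajectories"):
        raise ValueError(f"unknown bootstrap method {method!r}")
    kT = kT_kJmol(dataset.temperature)
    centers, counts = _histograms(dataset, n_bins, xi_range)
    _check_overlap(dataset, counts)
    k = np.array([w.force_constant for w in dataset.windows])
    x0 = np.array([w.center for w in dataset.windows])
    biases = 0.5 * k[:, None] * (centers[None, :] - x0[:, None]) ** 2
    n_win = counts.shape[0]
    N = counts.sum(axis=1)
    rng = np.random.default_rng(seed)
    if method == "trajectories":
        # parametric bootstrap: each round redraws every window's
        # histogram from its estimated biased distribution, so sparse
        # overlap bins fluctuate realistically (including zero counts)
        log_p_full, _ = _solve_wham(centers, counts, biases, kT, tolerance, max_iter)
        with np.errstate(invalid="ignore"):
            biased = np.exp(log_p_full[None, :] - biases / kT)
        biased = np.nan_to_num(biased)
        biased /= biased.sum(axis=1, keepdims=True)
    profiles = []
    f_warm = None
    for _ in range(rounds):
        if method == "histograms":
            w = rng.dirichlet(np.ones(n_win)) * n_win
            wc = counts * w[:, None]
        elif method == "trajectories":
            wc = np.array(
                [rng.multinomial(int(N[i]), biased[i]) for i in range(n_win)],
                dtype=float,
            )
        else:
            wc = rng.gamma(shape=counts)
            wc *= (N / np.clip(wc.sum(axis=1), 1e-300, None))[:, None]
        keep = wc.sum(axis=1) > 0
        log_p, f_warm_full = _solve_wham(
            centers, wc[keep], biases[keep], kT, tolerance, max_iter,
            f_init=None if f_warm is None else f_warm[keep],
        )
        f_warm = np.zeros(n_win)
        f_warm[keep] = f_warm_full
        with np.errstate(invalid="ignore"):
            G = -kT * log_p
        G = G - np.nanmin(G)
        profiles.append(G)
    profiles = np.array(profiles)
    finite = np.isfinite(profiles)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(finite, profiles, np.nan), axis=0)
        sd = np.nanstd(np.where(finite, profiles, np.nan), axis=0)
    mean = mean - np.nanmin(mean)
    return PMF(grid=centers, G=mean, err=sd, temperature=dataset.temperature)


def pore_free_energy(
    pmf: PMF,
    flat_region=(0.15, 0.35),
    pore_region=(0.85, 1.0),
):
    """Pore free energy dG_pore (kJ/mol) and its propagated error.

    dG_pore = mean of G over the open-pore plateau minus the minimum of
    G over the flat-membrane region.  Returns (dG, err).
    """
    g = pmf.grid
    half_bin = 0.5 * float(np.median(np.diff(g))) if len(g) > 1 else 0.0
    for lo, hi, name in [(*flat_region, "flat"), (*pore_region, "pore")]:
        if lo < g.min() - half_bin - 1e-9 or hi > g.max() + half_bin + 1e-9:
            raise ValueError(f"{name} region [{lo}, {hi}] outside PMF grid "
                             f"[{g.min():.3f}, {g.max():.3f}]")
    flat = (g >= flat_region[0]) & (g <= flat_region[1]) & np.isfinite(pmf.G)
    pore = (g >= pore_region[0]) & (g <= pore_region[1]) & np.isfinite(pmf.G)
    if not flat.any() or not pore.any():
        raise ValueError("no populated PMF bins inside the requested regions")
    i_min = np.flatnonzero(flat)[np.argmin(pmf.G[flat])]
    g_flat = pmf.G[i_min]
    g_pore = float(np.mean(pmf.G[pore]))
    dg = g_pore - g_flat
    err = float(np.hypot(np.mean(pmf.err[pore]), pmf.err[i_min]))
    return dg, err


def sphere_area(radius_nm: float) -> float:
    """Surface area (nm^2) of a sphere, e.g. a giant unilamellar vesicle."""
    return 4.0 * np.pi * radius_nm**2


def disc_area(diameter_nm: float) -> float:
    """Area (nm^2) of a disc, e.g. a black lipid membrane spanning a hole."""
    return np.pi * (diameter_nm / 2.0) ** 2


def area_scaled_dg(
    dg_pore: float,
    area_exp_nm2: float,
    area_sim_nm2: float = 45.0,
    temperature: float = 300.0,
) -> float:
    """Scale a simulation-box pore free energy to a membrane of area A_exp.

    dG_exp = dG_pore - kT ln(A_exp / A_sim), all in kJ/mol.  Default
    A_sim of 45 nm^2 corresponds to a 128-lipid simulation patch.
    """
    if area_exp_nm2 <= 0 or area_sim_nm2 <= 0:
        raise ValueError("areas must be positive")
    return dg_pore - kT_kJmol(temperature) * np.log(area_exp_nm2 / area_sim_nm2)


def pore_probability(dg_kJmol: float, temperature: float = 300.0) -> float:
    """Two-state open-pore probability ``1 / (1 + exp(dG / kT))``."""
    x = dg_kJmol / kT_kJmol(temperature)
    # guard overflow for very stable membranes
    if x > 500:
        return float(np.exp(-x))
    return float(1.0 / (1.0 + np.exp(x)))


# ---------------------------------------------------------------------------
# On-disk dialect: a window-list metadata file plus one two-column series
# file per window, compatible with common umbrella-sampling tooling.

def write_umbrella_dataset(dataset: UmbrellaDataset, directory, time_step: float = 1.0):
    """Write per-window series files and a ``windows.dat`` metadata file.

    Each series file holds two whitespace-separated columns (time, xi);
    the metadata file lists ``filename center force_constant`` per line.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta_lines = []
    for i, w in enumerate(dataset.windows):
        fname = f"window_{i:03d}.xvg"
        t = np.arange(len(w.samples)) * time_step
        np.savetxt(
            directory / fname,
            np.column_stack([t, w.samples]),
            header=f"umbrella window: center={w.center} force_constant={w.force_constant}",
        )
        meta_lines.append(f"{fname}\t{w.center}\t{w.force_constant}")
    meta = directory / "windows.dat"
    meta.write_text(
        "# file\tcenter\tforce_constant_kJ_mol\n" + "\n".join(meta_lines) + "\n"
    )
    return meta


def read_umbrella_dataset(meta_path, temperature: float = 323.0,
                          equilibration_fraction: float = 0.5) -> UmbrellaDataset:
    """Read the window-list dialect written by :func:`write_umbrella_dataset`."""
    meta_path = Path(meta_path)
    windows = []
    for line in meta_path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"malformed window-list line: {line!r}")
        fname, center, k = parts[0], float(parts[1]), float(parts[2])
        data = np.loadtxt(meta_path.parent / fname)
        samples = data[:, 1] if data.ndim == 2 else data
        windows.append(Window(center=center, force_constant=k, samples=samples))
    if not windows:
        raise ValueError(f"no windows listed in {meta_path}")
    return UmbrellaDataset(
        windows=windows,
        temperature=temperature,
        equilibration_fraction=equilibration_fraction,
    )
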