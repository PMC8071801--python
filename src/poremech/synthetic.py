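"""Synthetic inputs with the statistical structure of the real pipelines.

Three generators, all pure functions of (spec, seed):

* force-distance curves with stochastic breakthrough events whose
  forces follow the nucleation-model yield-force density;
* umbrella-sampling series Boltzmann-distributed under a known
  generating PMF plus harmonic window bias (independent draws by
  inverse-CDF on a fine grid, so WHAM is exercised exactly as on
  time-series input but at desk scale);
* toy membrane snapshots — phosphate planes, hydration water above a
  polar onset, optional water-filled cylindrical pore — sized after a
  128-lipid simulation patch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .constants import kT_kJmol
from .forcecurves import ForceCurve, YieldForceSample
from .nucleation import NucleationParams, sample_forces
from .observables import MembraneSnapshot
from .pmf import UmbrellaDataset, Window

__all__ = [
    "CurveSynthSpec",
    "PMFSpec",
    "SnapshotSpec",
    "sample_yield_forces",
    "generate_force_curve",
    "generate_umbrella_dataset",
    "generate_membrane_snapshot",
    "reference_pore_pmf",
    "default_window_layout",
    "DEFAULT_PARAMS",
]

#: Fixed experimental parameters of the AFM study conditions: soft
#: cantilever (0.060 N/m), 1 um/s approach, 3 kHz attempt frequency,
#: 20 nm tip, room temperature; (Gamma, S) of the bare POPC:POPG 1:1
#: bilayer.
DEFAULT_PARAMS = NucleationParams(
    gamma=6.93e-12,
    spreading_pressure=9.49e-3,
    tip_radius=20e-9,
    spring_constant=0.060,
    velocity=1e-6,
    attempt_frequency=3000.0,
    temperature=298.0,
)


def sample_yield_forces(
    params: NucleationParams, n: int, seed=None, condition: str = ""
) -> YieldForceSample:
    """Draw n yield forces (returned in nN) from the nucleation density."""
    forces_N = sample_forces(params, n, seed)
    return YieldForceSample(forces=forces_N / 1e-9, condition=condition)


# ---------------------------------------------------------------------------
# Force curves.

@dataclass(frozen=True)
class CurveSynthSpec:
    """Recipe for one synthetic approach curve.

    contact_stiffness is the membrane-on-substrate foundation stiffness
    (N/m); the observed ramp slope is the series stiffness of cantilever
    and membrane.  membrane_thickness_apparent (nm) is the distance
    travelled during the breakthrough plateau.  Distances are nm, forces
    nN; substrate contact has stiffness substrate_stiffness (N/m).
    """

    params: NucleationParams = DEFAULT_PARAMS
    contact_stiffness: float = 0.5
    membrane_thickness_apparent: float = 4.0
    noise_sd: float = 0.02  # nN
    sampling_step: float = 0.1  # nm
    approach_range: float = 50.0  # nm of pre-contact baseline
    substrate_stiffness: float = 1.0

    def __post_init__(self):
        if self.contact_stiffness <= 0:
            raise ValueError("contact_stiffness must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.membrane_thickness_apparent <= 0:
            raise ValueError("membrane_thickness_apparent must be positive")
        if self.sampling_step <= 0 or self.approach_range <= 0:
            raise ValueError("sampling_step and approach_range must be positive")

    @property
    def ramp_slope(self) -> float:
        """Series stiffness of cantilever and membrane foundation (nN/nm)."""
        k = self.params.spring_constant
        return k * self.contact_stiffness / (k + self.contact_stiffness)

    @property
    def substrate_slope(self) -> float:
        k = self.params.spring_constant
        return k * self.substrate_stiffness / (k + self.substrate_stiffness)


def generate_force_curve(
    spec: CurveSynthSpec, seed=None, breakthrough_force: float | None = None
) -> ForceCurve:
    """One approach curve: baseline, contact ramp, breakthrough plateau,
    substrate contact.

    The breakthrough force (nN) is sampled from the nucleation density
    unless given.  Ground truth is recorded in the metadata under
    ``true_*`` keys.
    """
    rng = np.random.default_rng(seed)
    if breakthrough_force is None:
        # consume one stream-coupled draw so curve noise and force are
        # both reproducible from the single seed
        f_b = float(sample_forces(spec.params, 1, rng.integers(2**31))[0] / 1e-9)
    else:
        f_b = float(breakthrough_force)
    k_ramp = spec.ramp_slope
    k_sub = spec.substrate_slope
    t_m = spec.membrane_thickness_apparent
    x_b = f_b / k_ramp  # indentation at breakthrough onset
    post = 2.0 / k_sub + 2.0  # room for substrate ramp past the plateau
    d = np.arange(spec.approach_range, -(x_b + t_m + post), -spec.sampling_step)
    x = -d  # indentation axis, 0 at contact
    force = np.where(x <= 0, 0.0, k_ramp * x)
    plateau = (x > x_b) & (x <= x_b + t_m)
    force[plateau] = f_b
    substrate = x > x_b + t_m
    force[substrate] = f_b + k_sub * (x[substrate] - x_b - t_m)
    if spec.noise_sd > 0:
        force = force + rng.normal(0.0, spec.noise_sd, size=len(force))
    meta = {
        "spring_constant": spec.params.spring_constant,
        "velocity": spec.params.velocity,
        "tip_radius_nm": spec.params.tip_radius / 1e-9,
        "true_breakthrough_force_nN": f_b,
        "true_contact_distance_nm": 0.0,
        "true_plateau_start_nm": -x_b,
        "true_plateau_stop_nm": -(x_b + t_m),
        "noise_sd_nN": spec.noise_sd,
    }
    return ForceCurve(distance=d, force=force, meta=meta)


# ---------------------------------------------------------------------------
# Umbrella sampling from a known PMF.

@dataclass
class PMFSpec:
    """A generating free-energy profile G(xi) on [0, 1], kJ/mol.

    The minimum is shifted to zero on construction.
    """

    grid: np.ndarray
    values: np.ndarray
    temperature: float = 323.0

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.values.shape:
            raise ValueError("grid and values must be equal-length 1-d arrays")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("PMF values must be finite")
        self.values = self.values - self.values.min()
        self._spline = CubicSpline(self.grid, self.values)

    def __call__(self, xi):
        return self._spline(np.clip(xi, self.grid[0], self.grid[-1]))


def reference_pore_pmf(
    dg_pore: float = 65.0,
    xi_mid: float = 0.55,
    width: float = 0.12,
    left_wall: float = 30.0,
    temperature: float = 323.0,
    n_grid: int = 401,
) -> PMFSpec:
    """A pore-formation-like profile: minimum near xi ~ 0.25 (flat
    membrane), sigmoidal rise, plateau at ``dg_pore`` for xi > ~0.8
    (open pore).  ``left_wall`` curves the profile up toward xi -> 0."""
    xi = np.linspace(0.0, 1.0, n_grid)
    g = dg_pore / (1.0 + np.exp(-(xi - xi_mid) / width))
    g = g + left_wall * np.clip(0.25 - xi, 0.0, None) ** 2
    return PMFSpec(grid=xi, values=g, temperature=temperature)


def default_window_layout():
    """The 24-window umbrella layout used for pore PMFs: centers
    0.065-0.625 in steps of 0.08 at k = 5000 kJ/mol, and 0.7-1.0 in
    steps of 0.02 at k = 10000 kJ/mol."""
    lo = np.linspace(0.065, 0.625, 8)
    hi = np.linspace(0.70, 1.00, 16)
    centers = np.concatenate([lo, hi])
    force_constants = np.concatenate([np.full(len(lo), 5000.0), np.full(len(hi), 10000.0)])
    return centers, force_constants


def generate_umbrella_dataset(
    pmf: PMFSpec,
    centers=None,
    force_constants=None,
    n_per_window: int = 5000,
    seed=None,
    equilibration_fraction: float = 0.0,
    n_grid: int = 4001,
) -> UmbrellaDataset:
    """Independent Boltzmann draws per window under G(xi) + bias.

    Sampling is inverse-CDF on a fine grid of the biased density, so the
    draws are uncorrelated — the WHAM estimator sees the same
    distributions as from a long, well-mixed time series.
    """
    if centers is None or force_constants is None:
        centers, force_constants = default_window_layout()
    centers = np.asarray(centers, dtype=float)
    force_constants = np.asarray(force_constants, dtype=float)
    if len(centers) != len(force_constants):
        raise ValueError("centers and force_constants must have equal length")
    if centers.min() < pmf.grid[0] - 1e-9 or centers.max() > pmf.grid[-1] + 1e-9:
        raise ValueError("PMF grid does not cover all window centers")
    if n_per_window < 1:
        raise ValueError("n_per_window must be >= 1")
    kT = kT_kJmol(pmf.temperature)
    rng = np.random.default_rng(seed)
    xi = np.linspace(pmf.grid[0], pmf.grid[-1], n_grid)
    g = pmf(xi)
    windows = []
    prev_density = None
    for c, k in zip(centers, force_constants):
        e = g + 0.5 * k * (xi - c) ** 2
        w = np.exp(-(e - e.min()) / kT)
        density = w / np.trapezoid(w, xi)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (density[1:] + density[:-1]) * np.diff(xi))])
        cdf /= cdf[-1]
        u = rng.uniform(size=n_per_window)
        samples = np.interp(u, cdf, xi)
        if prev_density is not None:
            overlap = np.trapezoid(np.minimum(prev_density, density), xi)
            if overlap < 1e-4:
                warnings.warn(
                    f"umbrella windows at {prev_c:.3f} and {c:.3f} have "
                    f"negligible overlap ({overlap:.2e})",
                    stacklevel=2,
                )
        prev_density, prev_c = density, c
        windows.append(Window(center=float(c), force_constant=float(k), samples=samples))
    return UmbrellaDataset(
        windows=windows,
        temperature=pmf.temperature,
        equilibration_fraction=equilibration_fraction,
    )


# ---------------------------------------------------------------------------
# Membrane snapshots.

@dataclass(frozen=True)
class SnapshotSpec:
    """Toy bilayer patch: phosphate planes at +-leaflet_z, hydration
    water filling |z| >= polar_onset, tail beads in the core, and an
    optional water-filled cylindrical pore of radius pore_radius
    through the slab.

    The polar onset sits below the phosphate plane because headgroup
    hydration water penetrates toward the carbonyl region; it is what
    makes the flat-membrane chain coordinate come out near 0.25 for the
    standard cylinder geometry.
    """

    n_lipids_per_leaflet: int = 64
    box: tuple = (6.4, 6.4, 6.0)
    leaflet_z: float = 1.9  # nm; phosphate planes at +-leaflet_z
    polar_onset: float = 1.15  # nm; water present for |z| >= polar_onset
    pore_radius: float | None = None
    pore_center: tuple = (None, None)  # defaults to box center
    water_density: float = 33.0  # molecules / nm^3
    jitter_sd: float = 0.0  # nm, phosphate out-of-plane jitter
    tails_per_lipid: int = 2

    def __post_init__(self):
        if self.n_lipids_per_leaflet < 1:
            raise ValueError("need at least one lipid per leaflet")
        if any(b <= 0 for b in self.box):
            raise ValueError("box lengths must be positive")
        if self.leaflet_z <= 0 or self.leaflet_z >= self.box[2] / 2:
            raise ValueError("leaflet_z must lie inside the box half-height")
        if not (0 < self.polar_onset <= self.leaflet_z):
            raise ValueError("polar_onset must be in (0, leaflet_z]")
        if self.pore_radius is not None:
            if self.pore_radius < 0:
                raise ValueError("pore_radius must be >= 0")
            if self.pore_radius > min(self.box[0], self.box[1]) / 2:
                raise ValueError("pore_radius larger than half the box")
        if self.water_density <= 0:
            raise ValueError("water_density must be positive")


def generate_membrane_snapshot(spec: SnapshotSpec, seed=None) -> MembraneSnapshot:
    """Build a snapshot according to `spec`; pure function of (spec, seed)."""
    rng = np.random.default_rng(seed)
    lx, ly, lz = spec.box
    pos, lab = [], []

    # phosphates on two jittered planes
    for sign in (+1.0, -1.0):
        xy = rng.uniform([0, 0], [lx, ly], size=(spec.n_lipids_per_leaflet, 2))
        z = sign * spec.leaflet_z + (
            rng.normal(0.0, spec.jitter_sd, spec.n_lipids_per_leaflet)
            if spec.jitter_sd > 0
            else 0.0
        )
        pos.append(np.column_stack([xy, np.broadcast_to(z, (spec.n_lipids_per_leaflet,))]))
        lab.extend(["P"] * spec.n_lipids_per_leaflet)

    # tail beads in the hydrophobic core
    n_tail = spec.n_lipids_per_leaflet * 2 * spec.tails_per_lipid
    if n_tail:
        txy = rng.uniform([0, 0], [lx, ly], size=(n_tail, 2))
        tz = rng.uniform(-0.9 * spec.polar_onset, 0.9 * spec.polar_onset, n_tail)
        pos.append(np.column_stack([txy, tz]))
        lab.extend(["T"] * n_tail)

    # hydration water in the two slabs |z| >= polar_onset
    slab_h = lz / 2 - spec.polar_onset
    n_w = rng.poisson(spec.water_density * lx * ly * slab_h)
    for sign in (+1.0, -1.0):
        wxy = rng.uniform([0, 0], [lx, ly], size=(n_w, 2))
        wz = sign * rng.uniform(spec.polar_onset, lz / 2, n_w)
        pos.append(np.column_stack([wxy, wz]))
        lab.extend(["W"] * n_w)

    # optional transmembrane water column
    if spec.pore_radius is not None and spec.pore_radius > 0:
        cx = spec.pore_center[0] if spec.pore_center[0] is not None else lx / 2
        cy = spec.pore_center[1] if spec.pore_center[1] is not None else ly / 2
        vol = np.pi * spec.pore_radius**2 * 2 * spec.polar_onset
        n_p = max(rng.poisson(spec.water_density * vol), 1)
        r = spec.pore_radius * np.sqrt(rng.uniform(size=n_p))
        phi = rng.uniform(0, 2 * np.pi, n_p)
        pz = rng.uniform(-spec.polar_onset, spec.polar_onset, n_p)
        pos.append(np.column_stack([cx + r * np.cos(phi), cy + r * np.sin(phi), pz]))
        lab.extend(["W"] * n_p)

    positions = np.vstack(pos)
    # wrap laterally into the box
    positions[:, 0] %= lx
    positions[:, 1] %= ly
    return MembraneSnapshot(positions=positions, labels=np.array(lab), box=spec.box)
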