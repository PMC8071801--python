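"""Breakthrough-force spectroscopy of supported lipid bilayers.

An approach force-distance curve on a membrane-covered substrate shows
(1) a flat zero-force baseline, (2) a contact point, (3) an elastic
contact ramp while the tip compresses the bilayer, (4) a discrete
breakthrough event with two kinks — the tip punches through the film —
and (5) hard contact with the solid support.  The yield force F is the
mean force over the points of the detected breakthrough event.

This module reads curves, removes baseline offset and tilt, locates the
contact point, detects breakthrough events from the smoothed first
derivative of force versus indentation, and summarizes yield-force
populations (median normalization, ECDF, boxplot statistics).

Conventions: distance is in nm and decreases along the approach (tip
moving toward the substrate); force is in nN, positive in compression.
Indentation ``x = -(d - d_contact)`` increases past the contact point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "ForceCurve",
    "BreakthroughEvent",
    "YieldForceSample",
    "ContactNotFoundError",
    "read_force_curve",
    "read_force_curves",
    "write_force_curve",
    "baseline_correct",
    "detect_contact_point",
    "detect_breakthrough",
    "analyze_curve",
    "normalize_yield_forces",
    "ecdf",
    "boxplot_stats",
]


class ContactNotFoundError(RuntimeError):
    """Raised when no contact point can be located on a curve."""


@dataclass
class ForceCurve:
    """One approach force-distance trace with cantilever metadata.

    meta carries at least ``spring_constant`` (N/m), ``velocity`` (m/s)
    and ``tip_radius`` (nm); ground-truth keys from the synthetic
    generator (``true_*``) ride along when present.
    """

    distance: np.ndarray  # nm, approach order (decreasing)
    force: np.ndarray  # nN
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.distance = np.asarray(self.distance, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.distance.shape != self.force.shape:
            raise ValueError("distance and force series must have equal length")
        # store in approach order: distance decreasing
        if len(self.distance) > 1 and self.distance[0] < self.distance[-1]:
            self.distance = self.distance[::-1]
            self.force = self.force[::-1]

    def __len__(self):
        return len(self.distance)


@dataclass
class BreakthroughEvent:
    """A detected breakthrough: contiguous indices, their mean force, and
    the distance travelled during the event (apparent jump)."""

    start: int
    stop: int  # exclusive
    yield_force: float  # nN
    jump_distance: float  # nm

    @property
    def n_points(self) -> int:
        return self.stop - self.start


@dataclass
class YieldForceSample:
    """A population of yield forces (nN) for one condition."""

    forces: np.ndarray
    condition: str = ""
    normalized: bool = False
    reference_median: float | None = None

    def __post_init__(self):
        self.forces = np.asarray(self.forces, dtype=float)
        if len(self.forces) and np.any(self.forces <= 0):
            raise ValueError("yield forces must be positive")
        if self.normalized and self.reference_median is None:
            raise ValueError("normalized sample must record its reference median")

    @property
    def median(self) -> float:
        return float(np.median(self.forces))

    def __len__(self):
        return len(self.forces)


# ---------------------------------------------------------------------------
# I/O: two-column whitespace text with '# key=value' metadata header.

_REQUIRED_META = ("spring_constant", "velocity")


def write_force_curve(curve: ForceCurve, path):
    path = Path(path)
    lines = [f"# {k}={v}" for k, v in curve.meta.items()]
    lines.append("# columns=distance_nm force_nN")
    for d, f in zip(curve.distance, curve.force):
        lines.append(f"{d:.6f}\t{f:.6f}")
    path.write_text("\n".join(lines) + "\n")


def read_force_curve(path) -> ForceCurve:
    """Read one curve in the two-column dialect; raises on malformed rows."""
    path = Path(path)
    meta = {}
    dist, force = [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                try:
                    meta[k.strip()] = float(v)
                except ValueError:
                    meta[k.strip()] = v.strip()
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path.name}:{lineno}: expected two columns, got {line!r}")
        try:
            d = float(parts[0])
            f = float(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path.name}:{lineno}: non-numeric value in {line!r}") from exc
        dist.append(d)
        force.append(f)
    for key in _REQUIRED_META:
        if key not in meta:
            raise KeyError(f"{path.name}: missing required metadata key {key!r}")
    if not dist:
        warnings.warn(f"{path.name}: header only, no data rows", stacklevel=2)
        return ForceCurve(np.array([]), np.array([]), meta)
    return ForceCurve(np.array(dist), np.array(force), meta)


def read_force_curves(path, pattern: str = "*.txt") -> list[ForceCurve]:
    """Read all curves in a directory (or a single file)."""
    path = Path(path)
    if path.is_file():
        return [read_force_curve(path)]
    files = sorted(path.glob(pattern))
    if not files:
        raise FileNotFoundError(f"no curve files matching {pattern!r} under {path}")
    return [read_force_curve(f) for f in files]


def read_force_curves_csv(path) -> list[ForceCurve]:
    """Read a generic CSV with named columns distance_nm, force_nN and
    optional curve_id to hold several curves."""
    df = pd.read_csv(path)
    if "distance_nm" not in df or "force_nN" not in df:
        raise KeyError("CSV must have columns distance_nm and force_nN")
    meta = {"spring_constant": np.nan, "velocity": np.nan}
    groups = df.groupby("curve_id") if "curve_id" in df else [(0, df)]
    return [
        ForceCurve(g["distance_nm"].to_numpy(), g["force_nN"].to_numpy(), dict(meta))
        for _, g in groups
    ]


# ---------------------------------------------------------------------------
# Curve processing.

def _baseline_slice(curve: ForceCurve, baseline_fraction: float) -> slice:
    n = max(int(len(curve) * baseline_fraction), 20)
    if n > len(curve):
        raise ValueError("curve too short for baseline estimation (need >= 20 samples)")
    return slice(0, n)


def baseline_correct(curve: ForceCurve, baseline_fraction: float = 0.3) -> ForceCurve:
    """Remove offset and linear tilt fitted over the pre-contact region.

    The baseline region is the first ``baseline_fraction`` of the
    approach (largest tip-sample distances).  Raises if that region
    turns out to contain the contact point of the corrected curve.
    """
    sl = _baseline_slice(curve, baseline_fraction)
    d = curve.distance[sl]
    f = curve.force[sl]
    coeff = np.polyfit(d, f, 1)
    corrected = curve.force - np.polyval(coeff, curve.distance)
    out = ForceCurve(curve.distance.copy(), corrected, dict(curve.meta))
    out.meta["baseline_slope_removed"] = float(coeff[0])
    out.meta["baseline_offset_removed"] = float(coeff[1])
    out.meta["baseline_n"] = sl.stop
    try:
        idx = detect_contact_point(out)
    except ContactNotFoundError:
        return out
    if idx < sl.stop:
        raise ValueError(
            f"baseline region (first {sl.stop} samples) overlaps the detected "
            f"contact point at index {idx}; reduce baseline_fraction"
        )
    return out


def baseline_noise(curve: ForceCurve, baseline_fraction: float = 0.3) -> float:
    """Standard deviation of the force over the baseline region (nN)."""
    sl = _baseline_slice(curve, baseline_fraction)
    return float(np.std(curve.force[sl]))


def detect_contact_point(
    curve: ForceCurve,
    noise_factor: float = 3.0,
    persistence: int = 5,
    baseline_fraction: float = 0.3,
) -> int:
    """Index of the contact point on a baseline-corrected curve.

    Coarse stage: first index opening a run of ``persistence``
    consecutive samples above ``noise_factor`` times the baseline noise.
    Refinement: a line is fitted to the contact ramp just after the
    crossing and extrapolated back to zero force; the returned index is
    the sample nearest that intercept.
    """
    sigma = baseline_noise(curve, baseline_fraction)
    thr = max(noise_factor * sigma, 1e-9)
    above = curve.force > thr
    # first index starting `persistence` consecutive True values
    run = np.convolve(above.astype(int), np.ones(persistence, dtype=int), "valid")
    hits = np.flatnonzero(run == persistence)
    if len(hits) == 0:
        raise ContactNotFoundError("no contact point found (curve never leaves baseline)")
    i0 = int(hits[0])
    # refine: fit the ramp over a short stretch after the crossing and
    # extrapolate back to zero force; the crossing lags the true contact
    # by at most ~threshold/slope, so reject refinements further back
    fit_n = 50
    j1 = min(i0 + fit_n, len(curve))
    if j1 - i0 >= 5:
        d = curve.distance[i0:j1]
        f = curve.force[i0:j1]
        slope, inter = np.polyfit(d, f, 1)
        if slope < 0:  # force grows as distance decreases
            d0 = -inter / slope
            idx = int(np.argmin(np.abs(curve.distance - d0)))
            if i0 - fit_n <= idx <= i0:
                return idx
    return i0


def _smoothed_derivative(curve: ForceCurve, window: int, polyorder: int):
    """dF/dx with x the indentation axis (nN/nm), Savitzky-Golay smoothed."""
    step = float(np.median(np.abs(np.diff(curve.distance))))
    if step == 0:
        raise ValueError("degenerate distance axis")
    window = min(window if window % 2 == 1 else window + 1, len(curve) - 1)
    if window <= polyorder:
        raise ValueError("curve too short for the smoothing window")
    # distance decreases along approach, so dF/dx = -dF/dd
    return savgol_filter(curve.force, window, polyorder, deriv=1, delta=step)


def detect_breakthrough(
    curve: ForceCurve,
    derivative_threshold: float | None = None,
    min_points: int = 3,
    smooth_window: int = 31,
    smooth_order: int = 2,
    contact_index: int | None = None,
    baseline_fraction: float = 0.3,
) -> list[BreakthroughEvent]:
    """Detect breakthrough events after the contact point.

    An event is a maximal run of at least ``min_points`` samples whose
    smoothed force derivative with respect to indentation drops below
    ``derivative_threshold`` (nN/nm) — the force plateaus or falls while
    the tip keeps advancing, between the two kinks of the event.  The
    default threshold is five times the baseline derivative noise,
    capped at 60% of the estimated contact-ramp slope so that a noisy
    baseline cannot push the threshold above the ramp itself.

    Returns events in approach order; ``yield_force`` is the mean raw
    force over the run.
    """
    if derivative_threshold is not None and derivative_threshold <= 0:
        raise ValueError("derivative_threshold must be positive")
    if contact_index is None:
        contact_index = detect_contact_point(curve, baseline_fraction=baseline_fraction)
    deriv = _smoothed_derivative(curve, smooth_window, smooth_order)
    sl = _baseline_slice(curve, baseline_fraction)
    ramp = np.inf
    post = deriv[contact_index:]
    if np.any(post > 0):
        ramp = float(np.quantile(post[post > 0], 0.5))
    if derivative_threshold is None:
        noise_sd = float(np.std(deriv[sl]))
        # 5x the baseline derivative noise, kept within [0.25, 0.3] of
        # the contact-ramp slope: the floor stops the threshold from
        # vanishing on clean data, the cap keeps it far enough below the
        # ramp that correlated noise dips on the ramp stay above it
        derivative_threshold = max(5.0 * noise_sd, 1e-6)
        if np.isfinite(ramp):
            derivative_threshold = float(np.clip(derivative_threshold, 0.25 * ramp, 0.3 * ramp))

    candidate = deriv < derivative_threshold
    # exclude the smoothing-blended zone right after the contact kink
    candidate[: contact_index + smooth_window] = False
    sigma = float(np.std(curve.force[sl]))
    tol = max(2.5 * sigma, 1e-9)
    events: list[BreakthroughEvent] = []
    i = contact_index + 1
    n = len(curve)
    while i < n:
        if not candidate[i]:
            i += 1
            continue
        j = i
        while j < n and candidate[j]:
            j += 1
        if j - i >= min_points:
            # trim edge samples that the smoothing blended in from the
            # neighbouring ramps: keep points force-consistent with the
            # run median
            a, b = i, j
            med = float(np.median(curve.force[a:b]))
            while b - a > min_points and abs(curve.force[a] - med) > tol:
                a += 1
            while b - a > min_points and abs(curve.force[b - 1] - med) > tol:
                b -= 1
            events.append(
                BreakthroughEvent(
                    start=a,
                    stop=b,
                    yield_force=float(np.mean(curve.force[a:b])),
                    jump_distance=float(curve.distance[a] - curve.distance[b - 1]),
                )
            )
        i = j
    return events


def analyze_curve(curve: ForceCurve, **detect_kwargs):
    """Baseline-correct, find contact, detect events; returns
    (corrected_curve, contact_index, events)."""
    corrected = baseline_correct(curve)
    idx = detect_contact_point(corrected)
    events = detect_breakthrough(corrected, contact_index=idx, **detect_kwargs)
    return corrected, idx, events


# ---------------------------------------------------------------------------
# Population statistics.

def normalize_yield_forces(sample: YieldForceSample, reference: YieldForceSample) -> YieldForceSample:
    """Divide each force by the reference median (the same-cantilever
    bare-membrane population), making populations from different tips
    comparable."""
    if len(reference) == 0:
        raise ValueError("reference sample is empty")
    ref_med = reference.median
    if ref_med <= 0:
        raise ValueError(f"reference median must be positive, got {ref_med}")
    return YieldForceSample(
        forces=sample.forces / ref_med,
        condition=sample.condition,
        normalized=True,
        reference_median=ref_med,
    )


def ecdf(sample: YieldForceSample) -> pd.DataFrame:
    """Right-continuous empirical CDF as a step table (force, probability)."""
    if len(sample) == 0:
        raise ValueError("empty sample")
    x = np.sort(sample.forces)
    y = np.arange(1, len(x) + 1) / len(x)
    return pd.DataFrame({"force": x, "cumulative_probability": y})


def boxplot_stats(sample: YieldForceSample, whisker: float = 1.5) -> dict:
    """Quartiles, whisker limits at ``whisker`` x IQR beyond the box
    (~2.7 sigma for normal data), and the outliers beyond them."""
    if len(sample) < 5:
        raise ValueError("need at least 5 values for boxplot statistics")
    f = sample.forces
    q1, med, q3 = np.percentile(f, [25, 50, 75])
    iqr = q3 - q1
    lo_lim = q1 - whisker * iqr
    hi_lim = q3 + whisker * iqr
    inside = f[(f >= lo_lim) & (f <= hi_lim)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "whisker_limit_low": float(lo_lim),
        "whisker_limit_high": float(hi_lim),
        "outliers": f[(f < lo_lim) | (f > hi_lim)].tolist(),
        "n": len(f),
    }
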