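# Methods

This note records the models, numerical choices and validation logic of
`poremech`, and states precisely what the synthetic-data generators do
and do not emulate.

## Continuum nucleation model (`poremech.nucleation`)

The model treats rupture of a supported bilayer under an AFM tip as
thermally activated nucleation of a circular hole. With line tension Γ
(N), spreading pressure S (N/m), tip radius R and applied force F, the
hole energy is U(r) = 2πrΓ + πr²(S − F/2πR); above the spreading force
F₀ = 2πRS it has a barrier ΔU(F) = 2π²Γ²R/(F − F₀).

**Yield-force density.** Under constant loading rate dF/dt = Kν and
attempt frequency A, rupture is a first-passage process with hazard (per
unit force) h(F) = (A/Kν)·exp(−ΔU(F)/k_BT), survival
s(F) = exp(−∫_{F₀}^F h), and density P = h·s. (A literal transcription
of the distribution sometimes quoted for this model contains a
divergent `1 − exp(+ΔU/k_BT)` factor; the first-passage form used here
is the standard, convergent expression for an activated-rate process
with the same integration limits, and it reproduces the expected
behavior: onset at F₀, loading-rate-dependent median, right-skewed
shape.)

**Closed form.** With u = F − F₀ and c = 2π²Γ²R/k_BT, the hazard
integral is ∫₀^u e^{−c/u′}du′ = u·e^{−c/u} + c·Ei(−c/u); the unit tests
verify this against adaptive quadrature to 1e−8 relative. Sampling is
exact inverse-CDF: u = I⁻¹(−ln(1−p)·Kν/A), with the inverse computed by
log-log interpolation on a 4096-point grid plus three Newton steps in
log u.

**Fitting.** Default is maximum likelihood over (Γ, S) with R, K, ν, A,
T fixed (A is fixed at the cantilever resonance frequency by default;
whether to free it is exposed to the caller by simply fitting with a
different fixed value). Internally the parameters are scaled to pN and
mN/m for conditioning; a Nelder–Mead stage (robust to the flat valley
along correlated Γ–S directions) is followed by bounded L-BFGS-B, with
S bounded so F₀ stays below the smallest observed force. Standard
errors come from the finite-difference Hessian of the negative
log-likelihood. The histogram least-squares variant
(Freedman–Diaconis bins) exists for fidelity with the fit procedure
used on real experimental histograms; on common samples it agrees with
MLE within ~2 joint standard errors. At n = 5000 the estimator is
unbiased with sampling SDs of ≈1.2% (Γ) and ≈2.4% (S), so a 5%
round-trip tolerance is a ≈2σ band.

**Defaults.** T = 298 K for the AFM side (room-temperature
experiments), R = 20 nm, K = 0.060 N/m, ν = 1 μm/s, A = 3 kHz — the
conditions of the force-spectroscopy study this pipeline mirrors.

## Force-curve analysis (`poremech.forcecurves`)

Curves are stored in approach order (distance decreasing, force
positive in compression); distance is a piezo-style axis, so the
contact ramp slope is the series stiffness of cantilever and membrane
foundation and cannot exceed K.

* **Baseline**: offset and linear tilt fitted over the first 30% of the
  approach (≥20 samples) and removed; an error is raised if the contact
  point later turns out to lie inside the baseline region.
* **Contact point**: first run of 5 consecutive samples above 3× the
  baseline noise SD, refined by fitting a line to the following ~50
  samples of the ramp and extrapolating to zero force (the coarse
  crossing lags the true contact by threshold/slope; refinements
  further back than the fit window are rejected). At 0.02 nN noise the
  95th-percentile error is ≤3 samples.
* **Breakthrough detection**: the force derivative with respect to
  indentation is computed with a Savitzky–Golay filter (window 31,
  order 2 — wide enough that derivative noise stays well below the ramp
  slope at 0.05 nN force noise on a 0.1 nm grid). Events are maximal
  runs of ≥ min_points (default 3) samples whose derivative falls below
  a threshold: by default 5× the baseline derivative noise, clamped to
  [0.25, 0.3] of the measured ramp slope — the floor keeps the
  threshold finite on noiseless data, the cap keeps correlated noise
  dips on the ramp from triggering. The half-window right after the
  contact kink is excluded (smoothing blends the kink into a
  plateau-like derivative). Run edges blended in from the neighbouring
  ramps are trimmed by force-consistency with the run median (±2.5× the
  noise SD). The yield force is the mean raw force over the run; when
  several events occur, all are reported and the first is used for
  statistics.
* **Statistics**: median normalization against a same-cantilever
  reference population (making different tips comparable), ECDF, and
  boxplot statistics with whiskers at 1.5×IQR beyond the quartiles
  (±2.70σ for normal data).

## Synthetic data (`poremech.synthetic`)

All generators are pure functions of (spec, seed).

* **Force curves**: zero-force baseline with Gaussian noise, contact
  ramp at the series stiffness, a plateau at a breakthrough force drawn
  from the nucleation density (loading rate Kν), a jump of
  `membrane_thickness_apparent` (default 4 nm) and a stiffer substrate
  ramp. Defaults: 0.1 nm sampling, 0.02 nN noise, 0.5 N/m membrane
  foundation stiffness — typical soft-cantilever AFM conditions. What
  is *not* emulated: tip-shape effects, adhesion on retract,
  drift/low-frequency noise, multiple-bilayer stacks; detector
  validation on these curves therefore demonstrates correctness of the
  algorithm, not robustness to every instrumental artifact.
* **Umbrella series**: independent inverse-CDF draws from the Boltzmann
  density of G(ξ) plus harmonic bias on a 4001-point grid. WHAM sees
  exactly the per-window distributions it would get from a long,
  well-decorrelated trajectory; autocorrelation (and hence the need for
  equilibration discards or correlation-time analysis) is deliberately
  absent. The default window layout is the 24-window pore-PMF scheme:
  centers 0.065–0.625 step 0.08 at k = 5000 kJ/mol and 0.7–1.0 step
  0.02 at k = 10 000 kJ/mol; T = 323 K.
* **Reference pore PMF** (`reference_pore_pmf`): sigmoid rise of height
  ΔG_pore = 65 kJ/mol centered at ξ = 0.55 with width 0.12 plus a
  shallow quadratic wall left of ξ = 0.25 — minimum near ξ ≈ 0.2–0.25
  (flat membrane), plateau beyond ξ ≈ 0.8 (open pore), rising gradually
  in between, as real pore-formation profiles do. The width was chosen
  once so that the profile's slope is spread over the sampled range
  rather than concentrated at the sparsely covered 0.625→0.7 gap of the
  window layout.
* **Membrane snapshots**: phosphate planes at ±1.9 nm (realistic P–P
  thickness) with optional jitter, tail beads in the core, hydration
  water filling |z| ≥ 1.15 nm, and optionally a water-filled cylinder
  through the slab. The water onset below the phosphate plane stands in
  for headgroup-region hydration; it is a geometry fixture tuned so the
  fixed 3-nm chain-coordinate cylinder sees ~8 polar slices on a flat
  membrane (ξ_ch ≈ 0.27), not a claim about real interfacial water
  structure.

## WHAM and errors (`poremech.pmf`)

Histograms use 200 bins on [0, 1] by default. The self-consistent WHAM
equations are solved by direct minimization of the (convex) WHAM
log-likelihood over the window offsets (L-BFGS with analytic gradient),
followed by self-consistent iterations until the maximum offset change
drops below the tolerance (default 1e−8, i.e. ~3e−8 kJ/mol). Windows
are required to overlap pairwise along the center ordering; the error
message names the first gap. Profiles are zeroed at their minimum;
unpopulated bins are NaN.

**Bayesian bootstrap.** Three schemes, all re-solving WHAM per round
and zeroing each round at its minimum before averaging:

* `samples` (default): Dirichlet(1,…,1) weights over the samples of
  each window, equivalent to Gamma(count) weights per histogram bin
  renormalized to the window total. This resamples within-window
  counting noise — the dominant error when each window is a single
  independent-sample series — and was verified against 20 independent
  replicate datasets (median true-SD/bootstrap-SD ≈ 1.0).
* `trajectories`: parametric — each round redraws every window's
  histogram from its estimated biased distribution, so even zero-count
  overlap bins fluctuate.
* `histograms`: one Dirichlet weight per whole window, the classic
  scheme for data consisting of several complete histograms per state.
  With one series per window it captures only between-window
  disagreement and understates pointwise errors ~3×, which is why it is
  not the default here.

**Pore free energy**: mean of G over the open-pore plateau region
(default ξ ∈ [0.85, 1.0]) minus the minimum over the flat region
(default ξ ∈ [0.15, 0.35]); the error combines the mean plateau error
and the error at the minimum in quadrature.

**Interpreting pointwise error bands.** The bootstrap SD is a pointwise
statement. Across the ~170 correlated bins of [0.1, 0.95] the maximum
deviation from a known truth is typically 2–3.5σ even for a perfectly
calibrated estimator (order statistics of dependent errors), so the
recovery tests assert the empirical 2σ coverage (≥85% pooled over
several datasets against a nominal ~95%) together with hard caps on the
maximum z and on the absolute deviation, rather than demanding every
bin inside 2σ. A systematic defect — wrong temperature, wrong bias
sign — produces z in the tens and fails all three immediately.

**Area scaling** uses T = 300 K by default: the standard reference
temperature for translating simulation-box pore free energies to
experimental membrane areas (GUV, black lipid membrane), independent of
the 323 K sampling temperature of the umbrella data.

## Membrane observables (`poremech.observables`)

The chain-coordinate cylinder is aligned with z (the membrane normal),
centered at z = 0, with minimum-image lateral distances. Slice
occupancy is occ(N) = 1 − (1 − ζ)^N, which satisfies the anchor values
occ(0) = 0 and occ(1) = ζ = 0.75 and saturates monotonically — the
coordinate here is an analysis-side evaluator, so only these anchors
(and monotonicity) matter, not the differentiable form needed to apply
bias forces during a simulation. The "auto" cylinder center maximizes
ξ_ch over a periodic lateral grid (0.1 nm default) with a deterministic
lowest-x-then-y tie-break; this is a static stand-in for the
dynamically tracking cylinder used when the coordinate is sampled
during MD. Thickness is the difference of mean phosphate z between
leaflets; area per lipid is the lateral box area over lipids per
leaflet; cylindrical density maps are mass-weighted histograms
normalized by annular bin volume 2πr·Δr·Δz.

## Problem sizes

The shipped tests and the acceptance script run at desk scale:
n = 5000 yield forces per fit (estimator SDs ≈1–2.5%), 500 synthetic
curves for detector validation, 24 umbrella windows × 5000 draws with
50 bootstrap rounds for PMF recovery. These sizes were chosen so each
statistical claim is tested at a few-σ margin; all scale linearly if
more precision is wanted.

## Known limitations

* The nucleation fit treats A as fixed; A and Kν are not separately
  identifiable from a single loading rate (only A/Kν enters).
* The spreading pressure S is a lump sum of four interfacial energies;
  the decomposition is not computed.
* WHAM input is binned; no MBAR-style binless estimator and no
  autocorrelation analysis are provided (the generators produce
  independent draws).
* Snapshot observables ingest single snapshots (PDB/CSV), not
  trajectory formats.
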