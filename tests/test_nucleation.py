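"""Continuum nucleation model: energies, yield-force density, fits."""

import numpy as np
import pytest
from scipy import integrate, optimize, stats

from poremech import nucleation as nuc
from poremech.nucleation import NucleationParams

from conftest import CONDITIONS


class TestHoleEnergetics:
    def test_zero_radius_costs_nothing(self, bare_bilayer_params):
        assert nuc.hole_energy(0.0, 2e-9, bare_bilayer_params) == 0.0

    def test_hole_energy_hand_value(self, bare_bilayer_params):
        # 2*pi*1nm*Gamma + pi*(1nm)^2*(S - F/(2*pi*R)) evaluated by hand
        u = nuc.hole_energy(1e-9, 2e-9, bare_bilayer_params)
        assert u == pytest.approx(2.34e-20, rel=5e-3)

    def test_no_barrier_at_threshold_force(self, bare_bilayer_params):
        # at F = 2*pi*R*S the quadratic term vanishes: U strictly increasing
        f0 = bare_bilayer_params.threshold_force
        r = np.linspace(0, 5e-9, 200)
        u = nuc.hole_energy(r, f0, bare_bilayer_params)
        assert np.all(np.diff(u) > 0)

    def test_critical_radius_hand_value(self, bare_bilayer_params):
        assert nuc.critical_radius(2e-9, bare_bilayer_params) == pytest.approx(
            1.08e-9, rel=5e-3
        )

    def test_critical_radius_decreases_with_force(self, bare_bilayer_params):
        forces = np.linspace(1.5e-9, 50e-9, 100)
        rc = nuc.critical_radius(forces, bare_bilayer_params)
        assert np.all(np.diff(rc) < 0)
        assert rc[-1] < 0.1e-9

    def test_below_threshold_rejected(self, bare_bilayer_params):
        with pytest.raises(ValueError, match="spreading force"):
            nuc.critical_radius(bare_bilayer_params.threshold_force, bare_bilayer_params)
        with pytest.raises(ValueError, match="spreading force"):
            nuc.barrier(1e-10, bare_bilayer_params)

    def test_barrier_hand_value_and_kT_scale(self, bare_bilayer_params):
        du = nuc.barrier(2e-9, bare_bilayer_params)
        assert du == pytest.approx(2.35e-20, rel=5e-3)
        assert du / bare_bilayer_params.kT == pytest.approx(5.7, abs=0.1)

    def test_barrier_is_hole_energy_at_critical_radius(self, bare_bilayer_params):
        for f in (1.3e-9, 2e-9, 5e-9):
            rc = nuc.critical_radius(f, bare_bilayer_params)
            assert nuc.barrier(f, bare_bilayer_params) == pytest.approx(
                nuc.hole_energy(rc, f, bare_bilayer_params), rel=1e-10
            )

    def test_barrier_quadruples_when_line_tension_doubles(self, bare_bilayer_params):
        p2 = NucleationParams(
            gamma=2 * bare_bilayer_params.gamma,
            spreading_pressure=bare_bilayer_params.spreading_pressure,
        )
        f = 3e-9
        assert nuc.barrier(f, p2) == pytest.approx(
            4 * nuc.barrier(f, bare_bilayer_params), rel=1e-12
        )

    def test_barrier_matches_numeric_maximum_for_random_parameters(self, rng):
        """The closed-form barrier equals the numerically located maximum
        of the hole energy for 100 random physical parameter sets."""
        for _ in range(100):
            p = NucleationParams(
                gamma=rng.uniform(2e-12, 15e-12),
                spreading_pressure=rng.uniform(2e-3, 15e-3),
                tip_radius=rng.uniform(10e-9, 60e-9),
            )
            f = p.threshold_force * rng.uniform(1.2, 5.0)
            rc = nuc.critical_radius(f, p)
            res = optimize.minimize_scalar(
                lambda r: -nuc.hole_energy(r, f, p),
                bounds=(0.0, 10 * rc),
                method="bounded",
                options={"xatol": rc * 1e-12},
            )
            assert nuc.barrier(f, p) == pytest.approx(-res.fun, rel=1e-8)


class TestYieldForceDistribution:
    def test_survival_limits(self, bare_bilayer_params):
        f0 = bare_bilayer_params.threshold_force
        assert nuc.survival(f0, bare_bilayer_params) == 1.0
        assert nuc.survival(0.5 * f0, bare_bilayer_params) == 1.0
        assert nuc.survival(100e-9, bare_bilayer_params) < 1e-12

    def test_survival_monotone_nonincreasing(self, bare_bilayer_params):
        f = np.linspace(0, 20e-9, 500)
        s = nuc.survival(f, bare_bilayer_params)
        assert np.all(np.diff(s) <= 1e-15)

    def test_closed_form_integral_matches_quadrature(self, bare_bilayer_params):
        """The Ei closed form of the hazard integral agrees with adaptive
        quadrature of exp(-barrier/kT) to high relative accuracy."""
        p = bare_bilayer_params
        c = nuc._barrier_scale(p)
        for f in (1.5e-9, 2e-9, 3e-9, 8e-9):
            q, _ = integrate.quad(
                lambda fp: np.exp(-nuc.barrier(fp, p) / p.kT),
                p.threshold_force * (1 + 1e-13),
                f,
                limit=300,
            )
            closed = nuc._hazard_integral(f - p.threshold_force, c)
            assert closed == pytest.approx(q, rel=1e-8)

    @pytest.mark.parametrize("label,gamma,s", CONDITIONS)
    def test_pdf_normalizes_to_one(self, label, gamma, s):
        p = NucleationParams(gamma=gamma, spreading_pressure=s)
        total, _ = integrate.quad(
            lambda f: nuc.pdf(f, p), p.threshold_force, 100e-9, limit=500
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_pdf_vanishes_at_threshold(self, bare_bilayer_params):
        f0 = bare_bilayer_params.threshold_force
        assert nuc.pdf(f0, bare_bilayer_params) == 0.0
        assert nuc.pdf(f0 * (1 + 1e-6), bare_bilayer_params) < 1e-3 / 1e-9

    def test_pdf_normalizes_for_random_parameters(self, rng):
        for _ in range(20):
            p = NucleationParams(
                gamma=rng.uniform(3e-12, 12e-12),
                spreading_pressure=rng.uniform(2e-3, 12e-3),
            )
            total, _ = integrate.quad(
                lambda f: nuc.pdf(f, p), p.threshold_force, 200e-9, limit=500
            )
            assert total == pytest.approx(1.0, abs=1e-5)

    def test_samples_follow_the_analytic_distribution(self, bare_bilayer_params):
        """CDF-transformed draws are uniform (exact inverse-CDF check)."""
        f = nuc.sample_forces(bare_bilayer_params, 10_000, seed=7)
        u = nuc.cdf(f, bare_bilayer_params)
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_all_samples_exceed_spreading_force(self, bare_bilayer_params):
        f = nuc.sample_forces(bare_bilayer_params, 2000, seed=3)
        assert np.all(f > bare_bilayer_params.threshold_force)
        # 2*pi*R*S = 1.19 nN for these parameters
        assert np.all(f > 1.19e-9)

    def test_sampling_is_reproducible(self, bare_bilayer_params):
        a = nuc.sample_forces(bare_bilayer_params, 100, seed=42)
        b = nuc.sample_forces(bare_bilayer_params, 100, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_invalid_sample_size_rejected(self, bare_bilayer_params):
        with pytest.raises(ValueError, match="n"):
            nuc.sample_forces(bare_bilayer_params, 0)

    def test_nonphysical_parameters_name_the_field(self):
        with pytest.raises(ValueError, match="gamma"):
            NucleationParams(gamma=-1e-12, spreading_pressure=9e-3)
        with pytest.raises(ValueError, match="temperature"):
            NucleationParams(gamma=1e-12, spreading_pressure=9e-3, temperature=0)

    def test_larger_line_tension_shifts_forces_up(self):
        """Stochastic ordering: raising Gamma at fixed S moves the whole
        yield-force distribution to larger forces."""
        lo = NucleationParams(gamma=4.91e-12, spreading_pressure=5e-3)
        hi = NucleationParams(gamma=8.49e-12, spreading_pressure=5e-3)
        f = np.linspace(0.7e-9, 30e-9, 400)
        assert np.all(nuc.cdf(f, hi) <= nuc.cdf(f, lo) + 1e-12)

    def test_median_force_increases_with_loading_rate(self, bare_bilayer_params):
        base = bare_bilayer_params
        faster = NucleationParams(
            gamma=base.gamma, spreading_pressure=base.spreading_pressure,
            velocity=10 * base.velocity,
        )
        med = lambda p: np.median(nuc.sample_forces(p, 4000, seed=11))
        assert med(faster) > med(base)

    def test_lower_attempt_frequency_acts_like_faster_loading(self, bare_bilayer_params):
        base = bare_bilayer_params
        slow_attempts = NucleationParams(
            gamma=base.gamma, spreading_pressure=base.spreading_pressure,
            attempt_frequency=base.attempt_frequency / 10,
        )
        fast_loading = NucleationParams(
            gamma=base.gamma, spreading_pressure=base.spreading_pressure,
            velocity=10 * base.velocity,
        )
        f = np.linspace(1.3e-9, 30e-9, 200)
        np.testing.assert_allclose(
            nuc.cdf(f, slow_attempts), nuc.cdf(f, fast_loading), rtol=1e-10
        )


class TestFitting:
    @pytest.mark.parametrize("label,gamma,s", CONDITIONS)
    def test_mle_recovers_generating_parameters(self, label, gamma, s):
        truth = NucleationParams(gamma=gamma, spreading_pressure=s)
        forces = nuc.sample_forces(truth, 5000, seed=1)
        result = nuc.fit(forces, truth)
        assert result.converged
        assert result.gamma == pytest.approx(gamma, rel=0.05)
        assert result.spreading_pressure == pytest.approx(s, rel=0.05)
        assert result.gamma_se > 0 and result.spreading_pressure_se > 0

    def test_loglik_at_truth_beats_perturbed_parameters(self, bare_bilayer_params):
        forces = nuc.sample_forces(bare_bilayer_params, 5000, seed=21)
        result = nuc.fit(forces, bare_bilayer_params)
        ll_hat = float(np.sum(nuc.log_pdf(forces, result.params)))
        perturbed = NucleationParams(
            gamma=result.gamma * 1.1,
            spreading_pressure=result.spreading_pressure,
        )
        assert ll_hat >= float(np.sum(nuc.log_pdf(forces, perturbed)))

    def test_histogram_fit_agrees_with_mle(self, bare_bilayer_params):
        forces = nuc.sample_forces(bare_bilayer_params, 10_000, seed=13)
        mle = nuc.fit(forces, bare_bilayer_params, method="mle")
        hist = nuc.fit(forces, bare_bilayer_params, method="histogram")
        assert hist.gamma == pytest.approx(mle.gamma, abs=2 * max(mle.gamma_se, 1e-14) + 0.03 * mle.gamma)
        assert hist.spreading_pressure == pytest.approx(
            mle.spreading_pressure,
            abs=2 * max(mle.spreading_pressure_se, 1e-6) + 0.03 * mle.spreading_pressure,
        )

    def test_small_samples_warn(self, bare_bilayer_params):
        forces = nuc.sample_forces(bare_bilayer_params, 50, seed=2)
        with pytest.warns(UserWarning, match="fewer than 100"):
            nuc.fit(forces, bare_bilayer_params)

    def test_fit_rejects_bad_input(self, bare_bilayer_params):
        with pytest.raises(ValueError):
            nuc.fit(np.array([1e-9, 2e-9]), bare_bilayer_params)
        with pytest.raises(ValueError):
            nuc.fit(np.array([1e-9, -1e-9, 2e-9, 3e-9, 4e-9]), bare_bilayer_params)


class TestBootstrap:
    def test_intervals_reproducible_and_ordered(self, bare_bilayer_params):
        forces = nuc.sample_forces(bare_bilayer_params, 400, seed=5)
        a = nuc.bootstrap_ci(forces, bare_bilayer_params, n_boot=25, seed=8)
        b = nuc.bootstrap_ci(forces, bare_bilayer_params, n_boot=25, seed=8)
        assert a["gamma_ci"] == b["gamma_ci"]
        assert a["gamma_ci"][0] <= a["gamma"] <= a["gamma_ci"][1]
        assert a["spreading_pressure_ci"][0] <= a["spreading_pressure_ci"][1]

    def test_single_round_degenerate_interval_warns(self, bare_bilayer_params):
        forces = nuc.sample_forces(bare_bilayer_params, 300, seed=5)
        with pytest.warns(UserWarning, match="degenerate"):
            out = nuc.bootstrap_ci(forces, bare_bilayer_params, n_boot=1, seed=0)
        assert out["gamma_ci"][0] == out["gamma_ci"][1]

    def test_coverage_of_the_generating_truth(self, bare_bilayer_params):
        """The 95% percentile interval covers the generating parameters in
        most simulated repetitions (allowing small-n interval error)."""
        hits_gamma = hits_s = 0
        reps = 20
        for i in range(reps):
            forces = nuc.sample_forces(bare_bilayer_params, 600, seed=100 + i)
            ci = nuc.bootstrap_ci(forces, bare_bilayer_params, n_boot=50, seed=200 + i)
            lo, hi = ci["gamma_ci"]
            hits_gamma += lo <= bare_bilayer_params.gamma <= hi
            lo, hi = ci["spreading_pressure_ci"]
            hits_s += lo <= bare_bilayer_params.spreading_pressure <= hi
        assert hits_gamma >= int(0.8 * reps)
        assert hits_s >= int(0.8 * reps)
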