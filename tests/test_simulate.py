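"""Synthetic-data generator: sampling fidelity, rendering physics, binding data."""

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter

import kymoclear as kc
from kymoclear.simulate import (
    MotorPopulation,
    RPA_POPULATION,
    cleared_fraction,
    lognormal_from_quartiles,
    lognormal_quartiles,
    profile_snr,
    sample_motors,
    simulate_dissociation,
    simulate_titration,
)


class TestMotorSampling:
    def test_scale_parameter_against_monte_carlo_quartiles(self):
        # the fitted (mu, sigma) must reproduce their own theoretical
        # quartiles in a large Monte-Carlo sample
        mu, sigma = lognormal_from_quartiles(63.0, 28.0, 117.0)
        q1_t, med_t, q3_t = lognormal_quartiles(mu, sigma)
        draws = np.random.default_rng(0).lognormal(mu, sigma, 1_000_000)
        q1, med, q3 = np.percentile(draws, [25, 50, 75])
        assert med == pytest.approx(63.0, rel=0.005)
        assert q1 == pytest.approx(q1_t, rel=0.01)
        assert q3 == pytest.approx(q3_t, rel=0.01)
        # the quartile *ratio* is matched exactly by construction
        assert q3_t / q1_t == pytest.approx(117.0 / 28.0, rel=1e-9)

    def test_sampled_population_matches_configured_median(self):
        pop = MotorPopulation(63.0, (28.0, 117.0), 3.9, (2.7, 5.1), 10_000)
        cfg = kc.SimConfig(n_frames=10)
        motors = sample_motors(pop, cfg, seed=1)
        v = np.array([m.velocity_nt_s for m in motors])
        p = np.array([m.processivity_knt for m in motors])
        assert np.median(v) == pytest.approx(63.0, rel=0.02)
        assert np.median(p) == pytest.approx(3.9, rel=0.02)
        mu_v, s_v = pop.velocity_params()
        q1_t, _, q3_t = lognormal_quartiles(mu_v, s_v)
        q1, q3 = np.percentile(v, [25, 75])
        assert q1 == pytest.approx(q1_t, rel=0.05)
        assert q3 == pytest.approx(q3_t, rel=0.05)

    def test_degenerate_iqr_rejected(self):
        with pytest.raises(ValueError, match="infeasible IQR"):
            lognormal_from_quartiles(63.0, 50.0, 50.0)
        with pytest.raises(ValueError):
            MotorPopulation(63.0, (50.0, 50.0), 3.9, (2.7, 5.1), 10)

    def test_init_positions_uniform_and_deterministic(self):
        cfg = kc.SimConfig(n_frames=10)
        a = sample_motors(RPA_POPULATION, cfg, seed=5)
        b = sample_motors(RPA_POPULATION, cfg, seed=5)
        assert [m.init_position_nt for m in a] == [m.init_position_nt for m in b]
        inits = np.array([m.init_position_nt for m in a])
        assert inits.min() >= 0 and inits.max() <= cfg.molecule_length_nt


class TestRendering:
    def test_null_simulation_constant(self):
        cfg = kc.SimConfig(n_frames=5, bleach_rate_per_frame=0.0)
        stack, _ = kc.render_kymograph([], cfg, noise=False)
        g = stack.channels["green"]
        m = stack.channels["magenta"]
        assert np.allclose(g, g[0])  # green constant in time
        assert np.allclose(m, cfg.background)  # magenta background only

    def test_forced_front_advance_two_px_per_frame(self):
        cfg = kc.SimConfig(n_frames=12, bleach_rate_per_frame=0.0)
        v = 2.0 * cfg.nt_per_px / cfg.frame_interval_s  # 2 px per frame
        motor = kc.MotorGroundTruth("m0", 18000.0, v, 50.0, 0)
        stack, _ = kc.render_kymograph([motor], cfg, noise=False)
        widths = []
        for frame in range(2, 10):
            profile = stack.channels["magenta"][frame, cfg.row_center_px] - cfg.background
            above = np.nonzero(profile >= profile.max() / 2)[0]
            widths.append(above[-1] - above[0] + 1)
        growth = np.diff(widths)
        assert np.all(np.abs(growth - 2.0) <= 1)

    def test_noisy_mean_matches_noiseless_expectation(self):
        cfg = kc.SimConfig(n_frames=2, seed=3)
        motor = kc.MotorGroundTruth("m0", 15000.0, 100.0, 3.0, 0)
        clean, _ = kc.render_kymograph([motor], cfg, noise=False)
        rng = np.random.default_rng(11)
        acc = np.zeros_like(clean.channels["magenta"][1])
        n = 500
        for _ in range(n):
            noisy, _ = kc.render_kymograph([motor], cfg, noise=True, rng=rng)
            acc += noisy.channels["magenta"][1]
        mean = acc / n
        expect = clean.channels["magenta"][1]
        sem = np.sqrt(expect + cfg.read_noise_sd**2) / np.sqrt(n)
        z = np.abs(mean - expect) / sem
        # pointwise z-scores behave like |N(0,1)| across ~1200 pixels
        assert (z < 3.0).mean() > 0.99
        assert z.max() < 6.0

    def test_coverage_conservation_green_plus_magenta(self):
        cfg = kc.SimConfig(n_frames=8, bleach_rate_per_frame=0.0)
        motors = [
            kc.MotorGroundTruth("a", 8000.0, 80.0, 2.0, 0),
            kc.MotorGroundTruth("b", 9000.0, 120.0, 3.0, 1),  # overlaps a
        ]
        for frame in range(8):
            cleared = cleared_fraction(motors, cfg, frame * cfg.frame_interval_s)
            assert np.all(cleared <= 1.0 + 1e-12)  # union, never double-counted
            covered = 1.0 - cleared
            assert np.allclose(cleared + covered, 1.0)

    def test_psf_conserves_flux(self):
        cfg = kc.SimConfig(n_frames=3)
        img = np.zeros((cfg.n_rows, cfg.n_cols))
        img[cfg.row_center_px, cfg.barrier_px : cfg.anchor_px] = 100.0
        blurred = gaussian_filter(img, cfg.psf_sigma_px, mode="constant")
        assert blurred.sum() == pytest.approx(img.sum(), rel=1e-3)

    def test_seed_determinism_bit_identical(self):
        cfg = kc.SimConfig(n_frames=4, seed=9)
        motor = kc.MotorGroundTruth("m0", 12000.0, 60.0, 3.0, 0)
        s1, _ = kc.render_kymograph([motor], cfg, rng=9)
        s2, _ = kc.render_kymograph([motor], cfg, rng=9)
        assert np.array_equal(s1.channels["green"], s2.channels["green"])
        assert np.array_equal(s1.channels["magenta"], s2.channels["magenta"])

    def test_default_snr_near_five(self):
        assert profile_snr(kc.SimConfig(n_frames=2)) == pytest.approx(5.0, abs=0.3)

    def test_boundary_clipping_at_five_prime_end(self):
        cfg = kc.SimConfig(n_frames=20)
        motor = kc.MotorGroundTruth("m0", 2000.0, 100.0, 10.0, 0)
        lo, hi = motor.cleared_interval(300.0, cfg.frame_interval_s)
        assert lo >= 0.0 and hi == 2000.0
        assert motor.realized_extent_nt == 2000.0


class TestTitration:
    def test_half_saturation_identity(self):
        df = simulate_titration(39.0, 1.0, [0.0, 39.0], noise_sd=0.0, replicates=1)
        f = df.set_index("conc_nM")["fraction_bound"]
        assert f[0.0] == 0.0
        assert f[39.0] == pytest.approx(0.5)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            simulate_titration(39.0, 1.0, [-1.0, 2.0])

    def test_noise_clipped_to_unit_interval(self):
        df = simulate_titration(5.0, 1.0, [0.0, 1000.0], noise_sd=0.5, replicates=200, seed=0)
        assert df.fraction_bound.between(0.0, 1.0).all()

    def test_fit_recovers_kd_from_generated_data(self):
        concs = [0.0] + [float(2**k) for k in range(10)]
        df = simulate_titration(39.0, 1.0, concs, noise_sd=0.03, replicates=3, seed=4)
        wide = df.pivot_table(index="replicate", columns="conc_nM", values="fraction_bound")
        fit = kc.fit_hyperbolic(wide.columns.to_numpy(), wide.to_numpy())
        assert fit.success
        assert fit.kd_nM == pytest.approx(39.0, rel=0.10)


class TestDissociation:
    def test_zero_rate_treated_equals_control(self):
        t = np.arange(0, 20.0, 2.0)
        df = simulate_dissociation(0.0, t, noise_sd=0.0, replicates=1)
        wide = df.pivot_table(index="time_min", columns="condition", values="bound_fraction")
        assert np.allclose(wide["treated"], wide["control"])

    def test_half_life_identity(self):
        k = 0.2
        t_half = np.log(2) / k
        df = simulate_dissociation(k, [0.0, t_half], noise_sd=0.0, replicates=1)
        treated = df[(df.condition == "treated")].set_index("time_min")["bound_fraction"]
        assert treated[t_half] == pytest.approx(0.5)

    def test_log_linear_regression_recovers_rate(self):
        # independent oracle: straight-line fit to log bound fraction
        t = np.arange(0.0, 25.0, 2.5)
        df = simulate_dissociation(0.2, t, noise_sd=0.02, replicates=3, seed=8)
        mean = (
            df[df.condition == "treated"]
            .groupby("time_min")["bound_fraction"]
            .mean()
        )
        k_est = -np.polyfit(mean.index, np.log(np.clip(mean, 1e-6, None)), 1)[0]
        assert k_est == pytest.approx(0.2, rel=0.15)
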