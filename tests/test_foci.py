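"""Foci detection, intensity normalization, 3x3 readout, tether survival."""

import numpy as np
import pandas as pd
import pytest

import kymoclear as kc
from kymoclear.foci import (
    aggregate_intensity,
    detect_foci,
    foci_per_unit_length,
    focus_intensity_3x3,
    intensity_trace,
    tether_lifetime,
)
from kymoclear.kymo import MoleculeROI
from kymoclear.simulate import default_roi, simulate_foci_profile


class TestDetectFoci:
    def test_two_clean_gaussians_found_at_centers(self):
        profile = simulate_foci_profile(60, [20.0, 30.0], [10.0, 10.0], noise_sd=0.0)
        profile += np.random.default_rng(0).normal(0, 0.05, 60)  # avoid exact ties
        foci = detect_foci(profile, z_threshold=5.0)
        assert len(foci) == 2
        assert foci.position_px.to_numpy() == pytest.approx([20.0, 30.0], abs=0.5)

    def test_false_positive_rate_on_pure_noise(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(1000):
            profile = rng.normal(0.0, 1.0, 49)
            if len(detect_foci(profile, z_threshold=5.0)) > 0:
                hits += 1
        assert hits <= 10  # >= 99% of noise-only molecules are focus-free

    def test_recall_and_precision_on_planted_foci(self):
        rng = np.random.default_rng(2)
        tp = fp = fn = 0
        for _ in range(200)		:
            k = rng.integers(2, 5)
            true_pos = np.sort(rng.choice(np.arange(8, 120, 7), size=k, replace=False)).astype(float)
            noise_sd = 1.0
            profile = simulate_foci_profile(
                128, true_pos, np.full(k, 5.0 * noise_sd * 1.6), noise_sd=noise_sd, rng=rng
            )
            found = detect_foci(profile, z_threshold=4.0).position_px.to_numpy()
            matched = set()
            for p in true_pos:
                d = np.abs(found - p) if found.size else np.array([np.inf])
                if d.min() <= 2.0:
                    tp += 1
                    matched.add(int(np.argmin(d)))
                else:
                    fn += 1
            fp += max(0, found.size - len(matched))
        recall = tp / (tp + fn)
        precision = tp / (tp + fp)
        assert recall >= 0.95
        assert precision >= 0.95

    def test_empty_profile_gives_empty_list(self):
        assert len(detect_foci(np.zeros(30))) == 0


class TestFociPerUnitLength:
    ROI = MoleculeROI(6, 55, 9)

    def test_count_per_micron(self):
        # 4 foci on a 49 px = 13.1 um tether
        density = foci_per_unit_length(4, self.ROI, basis="um", pixel_size_um=0.267)
        assert density == pytest.approx(4 / (49 * 0.267))

    def test_zero_foci(self):
        assert foci_per_unit_length(0, self.ROI, basis="um", pixel_size_um=0.267) == 0.0

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            MoleculeROI(6, 6, 9)

    def test_poisson_density_recovery(self):
        # plant a Poisson(lambda) number of well-separated foci per molecule
        rng = np.random.default_rng(3)
        lam = 2.0
        counts = []
        n_mol = 120
        for _ in range(n_mol):
            k = min(rng.poisson(lam), 5)
            pos = rng.choice(np.arange(8, 120, 7), size=k, replace=False).astype(float)
            profile = simulate_foci_profile(128, pos, np.full(k, 8.0), noise_sd=1.0, rng=rng)
            counts.append(len(detect_foci(profile, z_threshold=4.0)))
        lam_true = np.mean(np.minimum(rng.poisson(lam, 100_000), 5))
        se = np.std(counts, ddof=1) / np.sqrt(n_mol)
        assert np.mean(counts) == pytest.approx(lam_true, abs=2 * se + 0.05)


class TestIntensityTrace:
    def test_bleach_only_movie_decays_exponentially(self):
        cfg = kc.SimConfig(n_frames=25, bleach_rate_per_frame=0.02)
        stack, _ = kc.render_kymograph([], cfg, noise=False)
        trace = intensity_trace(stack, default_roi(cfg), channel="green")
        expect = np.exp(-0.02 * np.arange(25))
        assert np.allclose(trace.values, expect, atol=0.02)

    def test_reference_frame_is_unity_and_renormalization_is_identity(self):
        cfg = kc.SimConfig(n_frames=8)
        stack, _ = kc.render_kymograph([], cfg, noise=False)
        trace = intensity_trace(stack, default_roi(cfg), channel="green")
        assert trace.values[0] == 1.0
        again = trace.normalized()
        assert np.allclose(again.values, trace.values)

    def test_terminal_green_loss_equals_cleared_fraction(self):
        # coverage bookkeeping: with bleaching off, the final normalized
        # green intensity is 1 - cleared/total
        cfg = kc.SimConfig(n_frames=30, bleach_rate_per_frame=0.0)
        motor = kc.MotorGroundTruth("m0", 15000.0, 100.0, 4.0, 2)
        stack, gt = kc.render_kymograph([motor], cfg, noise=False)
        trace = intensity_trace(stack, default_roi(cfg), channel="green")
        cleared = gt[gt.frame == 29].extent_nt.iloc[0]
        assert trace.values[-1] == pytest.approx(1.0 - cleared / cfg.molecule_length_nt, abs=0.02)

    def test_channel_anticorrelation_on_clearance(self):
        # terminal green loss equals magenta gain in coverage units
        cfg = kc.SimConfig(n_frames=30, bleach_rate_per_frame=0.0)
        motor = kc.MotorGroundTruth("m0", 15000.0, 100.0, 4.0, 2)
        stack, _ = kc.render_kymograph([motor], cfg, noise=False)
        roi = default_roi(cfg)
        green = intensity_trace(stack, roi, channel="green").values[-1]
        from kymoclear.kymo import extract_profile

        from scipy.special import erf

        row_mass = erf(1.5 / (np.sqrt(2) * cfg.psf_sigma_px))  # PSF flux in 3 rows
        mag = extract_profile(stack, roi, 29, "magenta").sum() / (
            cfg.gain_magenta * roi.length_px * row_mass
        )
        assert (1.0 - green) == pytest.approx(mag, rel=0.05)

    def test_sem_across_molecules(self):
        cfg = kc.SimConfig(n_frames=6)
        rng = np.random.default_rng(5)
        traces = []
        for _ in range(4):
            stack, _ = kc.render_kymograph([], cfg, noise=True, rng=rng)
            traces.append(intensity_trace(stack, default_roi(cfg), channel="green"))
        agg = aggregate_intensity(traces)
        assert (agg.n == 4).all()
        assert agg["sem"].iloc[1] > 0


class TestFocus3x3:
    def test_uniform_image(self):
        img = np.full((9, 9), 7.0)
        assert focus_intensity_3x3(img, (4, 4), background=2.0) == pytest.approx(5.0)

    def test_single_pixel_spike(self):
        bg, v = 3.0, 30.0
        img = np.full((9, 9), bg)
        img[4, 4] = v
        assert focus_intensity_3x3(img, (4, 4), background=bg) == pytest.approx(
            (v + 8 * bg) / 9 - bg
        )

    def test_border_rejected(self):
        with pytest.raises(ValueError):
            focus_intensity_3x3(np.zeros((9, 9)), (0, 4))


class TestTetherLifetime:
    def _state(self, rows):
        return pd.DataFrame(rows)

    def test_all_persist(self):
        state = np.ones((5, 20), dtype=bool)
        table = tether_lifetime(state, np.arange(20.0) * 5, challenge_time_s=25.0)
        assert np.allclose(table.fraction_surviving, 1.0)

    def test_all_break_at_challenge(self):
        state = np.ones((5, 20), dtype=bool)
        state[:, 6:] = False
        table = tether_lifetime(state, np.arange(20.0) * 5, challenge_time_s=25.0)
        assert table.fraction_surviving.iloc[-1] == 0.0
        assert table.time_s.max() <= 10.0

    def test_exponential_breakage_half_life(self):
        rng = np.random.default_rng(7)
        rate = 0.02  # per second
        times = np.arange(300.0)  # 1 s frames
        n_mol = 400
        state = np.ones((n_mol, times.size), dtype=bool)
        for i in range(n_mol):
            t_break = rng.exponential(1.0 / rate)
            state[i, times > 20.0 + t_break] = False
        table = tether_lifetime(state, times, challenge_time_s=20.0)
        # survival half-life within 15% of ln2 / rate
        t_half = np.interp(0.5, table.fraction_surviving[::-1], table.time_s[::-1])
        assert t_half == pytest.approx(np.log(2) / rate, rel=0.15)
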