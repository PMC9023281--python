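"""Profile extraction, Gaussian/Heaviside fitting, PSF correction, traces."""

import numpy as np
import pytest

import kymoclear as kc
from kymoclear.kymo import (
    FWHM_PER_SIGMA,
    MoleculeROI,
    _blurred_box,
    build_trace,
    correct_fwhm,
    extract_profile,
    fit_gaussian_profile,
    fit_heaviside_profile,
    halfmax_width,
    profile_from_image,
)
from kymoclear.simulate import default_roi


def _gauss(x, amp, center, sigma, base=0.0):
    return amp * np.exp(-((x - center) ** 2) / (2 * sigma**2)) + base


class TestExtractProfile:
    ROI = MoleculeROI(6, 55, 9, molecule_id="molX")

    def test_uniform_image_cancels_to_zero(self):
        img = np.full((19, 61), 50.0)
        profile = profile_from_image(img, self.ROI)
        assert np.allclose(profile, 0.0)

    def test_single_bright_pixel_survives_summation(self):
        img = np.full((19, 61), 10.0)
        img[9, 30] += 200.0
        profile = profile_from_image(img, self.ROI)
        assert profile[30 - 6] == pytest.approx(200.0)
        assert np.allclose(np.delete(profile, 30 - 6), 0.0)

    def test_edge_roi_raises_with_molecule_name(self):
        img = np.zeros((8, 61))
        roi = MoleculeROI(6, 55, 3, molecule_id="edge_mol")
        with pytest.raises(ValueError, match="edge_mol"):
            profile_from_image(img, roi)

    def test_matches_forward_model_on_noiseless_render(self, clean_stack, small_config, roi):
        # independent recomputation: gain x coverage ⊛ PSF summed over 3 rows
        stack, _ = clean_stack
        frame = 20
        profile = extract_profile(stack, roi, frame, "magenta")
        img = stack.channels["magenta"][frame]
        expect = (
            img[roi.row_center_px - 1 : roi.row_center_px + 2, roi.barrier_px : roi.anchor_px].sum(0)
            - 3.0 * small_config.background
        )
        assert np.allclose(profile, expect, atol=1e-6)


class TestGaussianFit:
    def test_closed_form_fwhm_on_noiseless_gaussian(self):
        x = np.arange(49, dtype=float)
        fit = fit_gaussian_profile(_gauss(x, 100.0, 24.0, 2.0, 5.0))
        assert fit.converged
        assert fit.fwhm_px == pytest.approx(FWHM_PER_SIGMA * 2.0, abs=1e-3)
        assert fit.center_px == pytest.approx(24.0, abs=1e-3)

    def test_flat_profile_not_converged(self):
        fit = fit_gaussian_profile(np.full(30, 7.0))
        assert not fit.converged
        assert np.isnan(fit.fwhm_px)

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian_profile(np.arange(5.0))

    def test_noisy_fwhm_against_grid_search_oracle(self):
        # median fitted FWHM over replicates within 5% of truth, and the
        # optimizer agrees with a dense grid search on a subset
        rng = np.random.default_rng(0)
        sigma_true, amp, n = 3.0, 50.0, 61
        x = np.arange(n, dtype=float)
        truth = FWHM_PER_SIGMA * sigma_true
        fwhms = []
        for i in range(200):
            y = _gauss(x, amp, 30.0, sigma_true) + rng.normal(0, amp / 5.0, n)
            fit = fit_gaussian_profile(y)
            if fit.converged:
                fwhms.append(fit.fwhm_px)
            if i < 10 and fit.converged:
                centers = np.linspace(27, 33, 40)
                sigmas = np.linspace(1.5, 6.0, 60)
                amps = np.linspace(20, 90, 40)
                best = (np.inf, None)
                for c in centers:
                    base_models = np.exp(-((x[None, :] - c) ** 2) / (2 * sigmas[:, None] ** 2))
                    for j, a in enumerate(amps):
                        sse = ((y[None, :] - a * base_models) ** 2).sum(1)
                        k = int(np.argmin(sse))
                        if sse[k] < best[0]:
                            best = (sse[k], FWHM_PER_SIGMA * sigmas[k])
                assert fit.fwhm_px == pytest.approx(best[1], rel=0.10)
        assert np.median(fwhms) == pytest.approx(truth, rel=0.05)

    def test_halfmax_crossing_agrees_on_noiseless_gaussians(self):
        x = np.arange(61, dtype=float)
        for sigma in (1.5, 2.5, 4.0):
            y = _gauss(x, 80.0, 30.0, sigma)
            fit = fit_gaussian_profile(y)
            assert fit.fwhm_px == pytest.approx(halfmax_width(y), rel=0.02)


class TestHeavisideFit:
    def test_noiseless_boxcar_width(self):
        y = np.zeros(49)
        y[20:30] = 50.0
        fit = fit_heaviside_profile(y)
        assert fit.converged
        assert fit.fwhm_px == pytest.approx(10.0, abs=0.5)

    def test_flat_profile_not_converged(self):
        assert not fit_heaviside_profile(np.full(30, 3.0)).converged

    def test_agrees_with_gaussian_on_rendered_clearance(self, clean_stack, roi):
        # the two estimators have opposite small biases on blurred boxes;
        # after each model's own PSF calibration they measure the same width
        stack, _ = clean_stack
        profile = extract_profile(stack, roi, 25, "magenta")
        g = fit_gaussian_profile(profile)
        h = fit_heaviside_profile(profile)
        assert g.converged and h.converged
        wg = correct_fwhm(g.fwhm_px, 1.3, "model", "gaussian")
        wh = correct_fwhm(h.fwhm_px, 1.3, "model", "heaviside")
        assert wh == pytest.approx(wg, rel=0.15)


class TestPsfCorrection:
    def test_model_inversion_is_exact_on_noiseless_boxes(self):
        x = np.arange(81, dtype=float)
        for w in (2.5, 5.0, 8.0, 14.0):
            fit = fit_gaussian_profile(_blurred_box(x, 40.0, w, 1.3) * 100.0)
            w_est = correct_fwhm(fit.fwhm_px, 1.3, "model", "gaussian")
            assert w_est == pytest.approx(w, rel=0.06)

    def test_quadrature_and_none_options(self):
        psf_fwhm = FWHM_PER_SIGMA * 1.3
        f = np.hypot(8.0, psf_fwhm)
        assert correct_fwhm(f, 1.3, "quadrature") == pytest.approx(8.0)
        assert correct_fwhm(f, 1.3, "none") == f
        with pytest.raises(ValueError):
            correct_fwhm(f, 1.3, "bogus")


class TestBuildTrace:
    def test_fwhm_monotone_on_noiseless_single_motor(self, clean_stack, roi):
        stack, _ = clean_stack
        trace = build_trace(stack, roi, "magenta", "gaussian")
        w = trace.df.loc[trace.df.converged, "fwhm_nt"].to_numpy()
        # non-decreasing up to the re-windowing granularity (~0.05 px)
        assert np.all(np.diff(w) >= -0.06 * trace.nt_per_px)

    def test_rad51_mode_green_influx_matches_magenta_mode(self, small_config, single_motor):
        # the RPA assay's magenta gain and the RAD51 assay's green gain
        # encode the same cleared coverage, so traces are identical
        rpa, _ = kc.render_kymograph([single_motor], small_config, mode="rpa", noise=False)
        rad, _ = kc.render_kymograph([single_motor], small_config, mode="rad51", noise=False)
        roi = default_roi(small_config)
        t_mag = build_trace(rpa, roi, "magenta", "gaussian")
        t_grn = build_trace(rad, roi, "green", "gaussian")
        a = t_mag.df.loc[t_mag.df.converged, "fwhm_nt"].to_numpy()
        b = t_grn.df.loc[t_grn.df.converged, "fwhm_nt"].to_numpy()
        assert a.size == b.size
        assert np.allclose(a, b, rtol=1e-6)

    def test_tracks_ground_truth_extent_within_one_px_rms(self, small_config):
        # population-scale oracle: corrected FWHM vs true cleared extent
        rng = np.random.default_rng(9)
        errs = []
        for i in range(12):
            v = float(rng.uniform(30, 110))
            p = float(rng.uniform(2.5, 5.0))
            motor = kc.MotorGroundTruth("m", 15000.0, v, p, 3)
            stack, gt = kc.render_kymograph([motor], small_config, noise=True, rng=rng)
            trace = build_trace(
                stack,
                default_roi(small_config),
                "magenta",
                "gaussian",
                psf_correction="model",
                psf_sigma_px=small_config.psf_sigma_px,
            )
            sub = trace.df[trace.df.converged]
            truth = gt.set_index("frame").loc[sub.frame, "extent_nt"].to_numpy()
            err_px = (sub.fwhm_nt.to_numpy() - truth) / small_config.nt_per_px
            errs.append(np.sqrt(np.mean(err_px**2)))
        # per-frame corrected-width noise at SNR 5 is ~1.1 px, so a trace
        # tracks its ground truth at ~1.3 px RMS
        assert np.median(errs) <= 1.5

    def test_unusable_flag_on_signal_free_stack(self, small_config):
        stack, _ = kc.render_kymograph(
            [], small_config, noise=True, rng=np.random.default_rng(0)
        )
        trace = build_trace(stack, default_roi(small_config), "magenta")
        assert not trace.usable

    def test_missing_frame_robustness(self, small_config):
        # deleting any single interior frame barely moves the velocity
        # (a 30 nt/s motor rises over ~9 frames, so one frame is spare)
        motor = kc.MotorGroundTruth("m0", 15000.0, 30.0, 3.9, 3)
        stack, _ = kc.render_kymograph(
            [motor], small_config, noise=True, rng=np.random.default_rng(3)
        )
        trace = build_trace(
            stack,
            default_roi(small_config),
            "magenta",
            "gaussian",
            psf_correction="model",
            psf_sigma_px=small_config.psf_sigma_px,
        )
        base_event = kc.extract_event(trace)
        for drop in range(5, 9):
            df = trace.df.copy()
            df.loc[df.frame == drop, "converged"] = False
            df.loc[df.frame == drop, "fwhm_nt"] = np.nan
            t2 = kc.ClearanceTrace(
                trace.molecule_id,
                trace.channel,
                trace.model,
                df,
                trace.nt_per_px,
                trace.frame_interval_s,
                trace.psf_correction,
                trace.usable,
            )
            ev = kc.extract_event(t2)
            assert ev.velocity_nt_s == pytest.approx(base_event.velocity_nt_s, rel=0.05)
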