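"""Kymograph containers and clearance-front profile fitting.

A *kymograph* here is a two-channel fluorescence image time series of a
single field of view containing surface-tethered ssDNA molecules.  A
translocating motor strips the ssDNA-binding protein coat and leaves a
growing protein-free gap.  Depending on the assay the gap is read out as a
gain of complementary-oligo signal (magenta channel) or as a gain of
RPA-GFP influx signal (green channel).  Either way the per-molecule,
per-frame observable is a one-dimensional intensity profile along the
molecule whose bright region marks the cleared interval.

The front-tracking procedure is:

1. sum the intensity over a ROI a few pixels wide (``extract_profile``),
   subtracting a per-column background estimated from flanking rows;
2. fit the profile with a Gaussian (``fit_gaussian_profile``) or a
   two-edge step/boxcar model (``fit_heaviside_profile``);
3. read the cleared extent off the full width at half maximum (FWHM) of
   the fit, frame by frame (``build_trace``).

Because the true cleared region is a top-hat convolved with the
microscope point spread function (PSF), the fitted FWHM is a biased
estimate of the cleared width, particularly when the width is comparable
to the PSF.  ``build_trace`` therefore supports an optional PSF
correction; see :func:`fwhm_calibration`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit
from scipy.special import erf

__all__ = [
    "KymographStack",
    "MoleculeROI",
    "ProfileFit",
    "ClearanceTrace",
    "extract_profile",
    "fit_gaussian_profile",
    "fit_heaviside_profile",
    "build_trace",
    "correct_fwhm",
    "fwhm_calibration",
    "halfmax_width",
    "FWHM_PER_SIGMA",
]

#: FWHM of a unit-sigma Gaussian.
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class KymographStack:
    """Calibrated two-channel image time series for one field of view.

    Parameters
    ----------
    channels
        Mapping of channel label (``"green"``, ``"magenta"``) to a float
        array indexed ``(frame, row, column)``.  All channels must share
        one shape with at least two frames.
    frame_interval_s
        Time between consecutive frames, seconds.
    nt_per_px
        Calibration: nucleotides of ssDNA per image column.
    meta
        Free-form metadata (simulation ground truth paths, geometry, ...).
    """

    channels: Mapping[str, np.ndarray]
    frame_interval_s: float
    nt_per_px: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("stack needs at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        (shape,) = shapes
        if len(shape) != 3 or shape[0] < 2:
            raise ValueError("channels must be (frame, row, column) with >= 2 frames")
        if self.frame_interval_s <= 0 or self.nt_per_px <= 0:
            raise ValueError("frame_interval_s and nt_per_px must be positive")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class MoleculeROI:
    """Region of interest for one tethered molecule.

    The 5' (biotin) end is tethered at the barrier, which sits at the
    *low* column index; the 3' end is at the downstream anchor.  Position
    along the molecule in nucleotides is ``(col - barrier_px) * nt_per_px``.
    """

    barrier_px: int
    anchor_px: int
    row_center_px: int
    width_px: int = 3
    molecule_id: str = "mol0"

    def __post_init__(self) -> None:
        if self.barrier_px >= self.anchor_px:
            raise ValueError(f"{self.molecule_id}: barrier_px must be < anchor_px")
        if self.width_px < 1 or self.width_px % 2 == 0:
            raise ValueError(f"{self.molecule_id}: width_px must be odd and positive")

    @property
    def length_px(self) -> int:
        return self.anchor_px - self.barrier_px


@dataclass
class ProfileFit:
    """Result of fitting one per-frame intensity profile.

    ``center_px``/``fwhm_px`` and the edges are in profile coordinates
    (column 0 at the barrier).  ``fwhm_px`` is the *as-fitted* width; any
    PSF correction is applied downstream by :func:`build_trace`.  When
    ``converged`` is False the geometric fields are NaN.
    """

    frame: int | None
    model: str
    center_px: float
    fwhm_px: float
    amplitude: float
    baseline: float
    r_squared: float
    converged: bool
    left_edge_px: float = np.nan
    right_edge_px: float = np.nan


def _failed_fit(frame: int | None, model: str, baseline: float = np.nan) -> ProfileFit:
    return ProfileFit(frame, model, np.nan, np.nan, np.nan, baseline, np.nan, False)


# ---------------------------------------------------------------------------
# profile extraction
# ---------------------------------------------------------------------------

#: gap (px) between the ROI edge and the background band, and band height
_BG_GAP = 5
_BG_BAND = 3


def extract_profile(
    stack: KymographStack, roi: MoleculeROI, frame: int, channel: str = "magenta"
) -> np.ndarray:
    """Background-subtracted 1-D intensity profile along a molecule.

    Sums the image over ``roi.width_px`` rows between barrier and anchor,
    then subtracts, per column, the median of flanking background rows
    (at least ``5`` px away from the ROI on either side) scaled by the
    ROI width.  Raises if the ROI or its background bands fall outside
    the image, naming the molecule.
    """
    image = stack.channels[channel][frame]
    return profile_from_image(image, roi)


def profile_from_image(image: np.ndarray, roi: MoleculeROI) -> np.ndarray:
    n_rows, n_cols = image.shape
    hw = roi.width_px // 2
    r0, r1 = roi.row_center_px - hw, roi.row_center_px + hw + 1
    if r0 < 0 or r1 > n_rows or roi.barrier_px < 0 or roi.anchor_px > n_cols:
        raise ValueError(f"ROI for molecule {roi.molecule_id!r} exceeds image bounds")
    cols = slice(roi.barrier_px, roi.anchor_px)
    raw = image[r0:r1, cols].sum(axis=0)

    bg_rows: list[np.ndarray] = []
    lo = r0 - _BG_GAP - _BG_BAND
    if lo >= 0:
        bg_rows.append(image[lo : r0 - _BG_GAP, cols])
    hi = r1 + _BG_GAP + _BG_BAND
    if hi <= n_rows:
        bg_rows.append(image[r1 + _BG_GAP : hi, cols])
    if not bg_rows:
        raise ValueError(
            f"ROI for molecule {roi.molecule_id!r} touches the image edge: "
            "no background rows available"
        )
    background = np.median(np.vstack(bg_rows), axis=0)
    return raw - roi.width_px * background


# ---------------------------------------------------------------------------
# profile models
# ---------------------------------------------------------------------------


def _gaussian(x: np.ndarray, amp: float, center: float, sigma: float, base: float):
    return amp * np.exp(-((x - center) ** 2) / (2.0 * sigma**2)) + base


def _r_squared(y: np.ndarray, resid: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - float(np.sum(resid**2)) / ss_tot


def fit_gaussian_profile(
    profile: np.ndarray, frame: int | None = None, min_amp_sd: float = 3.0
) -> ProfileFit:
    """Nonlinear least-squares Gaussian fit of an intensity profile.

    Free parameters: amplitude, center, sigma, baseline.  Initial guesses
    are the 10th percentile (baseline), max minus baseline (amplitude),
    the argmax (center), and a second-moment sigma estimate.  The fit
    *never raises*: failures and signal-free profiles (amplitude below 3x
    the residual standard deviation) come back with ``converged=False``.
    FWHM is ``2*sqrt(2 ln 2) * sigma``.
    """
    y = np.asarray(profile, dtype=float)
    n = y.size
    if n < 7:
        raise ValueError("profile too short to fit (need >= 7 samples)")
    x = np.arange(n, dtype=float)

    base0 = float(np.percentile(y, 10))
    amp0 = float(y.max() - base0)
    if amp0 <= 0:
        return _failed_fit(frame, "gaussian", base0)
    c0 = float(np.argmax(y))
    w = np.clip(y - base0, 0, None)
    tot = w.sum()
    if tot > 0:
        mu = float((w * x).sum() / tot)
        sig0 = float(np.sqrt(np.clip((w * (x - mu) ** 2).sum() / tot, 0.25, None)))
    else:
        sig0 = 2.0
    sig0 = min(sig0, n / 2.0)

    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                _gaussian,
                x,
                y,
                p0=[amp0, c0, sig0, base0],
                bounds=([0.0, -n, 0.3, -np.inf], [np.inf, 2 * n, 2.0 * n, np.inf]),
                maxfev=2000,
            )
    except (RuntimeError, ValueError):
        return _failed_fit(frame, "gaussian", base0)

    amp, center, sigma, base = (float(v) for v in popt)
    resid = y - _gaussian(x, *popt)
    resid_sd = float(resid.std())
    fwhm = FWHM_PER_SIGMA * abs(sigma)
    ok = amp >= min_amp_sd * resid_sd and -1.0 <= center <= n and fwhm <= 2.0 * n
    if not ok:
        return _failed_fit(frame, "gaussian", base)
    return ProfileFit(
        frame,
        "gaussian",
        center,
        fwhm,
        amp,
        base,
        _r_squared(y, resid),
        True,
        center - fwhm / 2.0,
        center + fwhm / 2.0,
    )


def fit_heaviside_profile(
    profile: np.ndarray, frame: int | None = None, min_amp_sd: float = 3.0
) -> ProfileFit:
    """Two-edge step (boxcar) fit by exhaustive scan over edge pairs.

    For every integer edge pair the optimal inside/outside levels are
    closed-form, so the SSE scan is exact; the minimizing pair is then
    refined to sub-pixel precision by local quadratic interpolation of
    the SSE along each edge.  The FWHM is the edge separation.  Same
    convergence policy as the Gaussian fit.
    """
    y = np.asarray(profile, dtype=float)
    n = y.size
    if n < 7:
        raise ValueError("profile too short to fit (need >= 7 samples)")

    S = np.concatenate(([0.0], np.cumsum(y)))
    S2 = np.concatenate(([0.0], np.cumsum(y * y)))
    total, total2 = S[-1], S2[-1]

    def sse_pair(left: np.ndarray, right: np.ndarray):
        """SSE for inside interval [left, right) with free levels."""
        k = right - left
        s_in = S[right] - S[left]
        m_in = s_in / k
        k_out = n - k
        with np.errstate(invalid="ignore", divide="ignore"):
            m_out = np.where(k_out > 0, (total - s_in) / np.maximum(k_out, 1), 0.0)
        return total2 - k * m_in**2 - k_out * m_out**2, m_in, m_out

    best = (np.inf, 1, 2)
    for left in range(n - 1):
        rights = np.arange(left + 1, n + 1)
        sse, _, _ = sse_pair(np.full_like(rights, left), rights)
        j = int(np.argmin(sse))
        if sse[j] < best[0]:
            best = (float(sse[j]), left, int(rights[j]))
    _, l0, r0 = best

    def sse_at(left: int, right: int) -> float:
        left = max(0, min(left, n - 1))
        right = max(left + 1, min(right, n))
        s, _, _ = sse_pair(np.array([left]), np.array([right]))
        return float(s[0])

    def subpixel(e: int, lo: float, mid: float, hi: float) -> float:
        denom = lo - 2 * mid + hi
        if denom <= 0:
            return float(e)
        return float(e + np.clip(0.5 * (lo - hi) / denom, -0.5, 0.5))

    l_ref = subpixel(l0, sse_at(l0 - 1, r0), sse_at(l0, r0), sse_at(l0 + 1, r0))
    r_ref = subpixel(r0, sse_at(l0, r0 - 1), sse_at(l0, r0), sse_at(l0, r0 + 1))

    _, m_in, m_out = sse_pair(np.array([l0]), np.array([r0]))
    amp = float(m_in[0] - m_out[0])
    base = float(m_out[0])
    model_y = np.full(n, base)
    model_y[l0:r0] = base + amp
    resid = y - model_y
    resid_sd = float(resid.std())
    fwhm = r_ref - l_ref
    if amp <= 0 or amp < min_amp_sd * resid_sd or fwhm <= 0 or fwhm >= n - 1:
        return _failed_fit(frame, "heaviside", base)
    return ProfileFit(
        frame,
        "heaviside",
        (l_ref + r_ref) / 2.0,
        fwhm,
        amp,
        base,
        _r_squared(y, resid),
        True,
        l_ref,
        r_ref,
    )


_FITTERS = {"gaussian": fit_gaussian_profile, "heaviside": fit_heaviside_profile}

#: amplitude threshold (in residual SDs) for first detection / re-acquisition
_ACQUIRE_SD = 4.0
#: below this corrected width the windowed-sum area read is the lower-
#: variance width estimator and replaces the fit-based value
_AREA_FIT_MAX_PX = 6.5


def halfmax_width(profile: np.ndarray) -> float:
    """Direct half-maximum crossing width with linear interpolation.

    Diagnostic estimator, independent of any model fit; used to
    cross-check fitted FWHM values.
    """
    y = np.asarray(profile, dtype=float)
    base = float(np.percentile(y, 10))
    half = base + (y.max() - base) / 2.0
    above = np.nonzero(y >= half)[0]
    if above.size == 0:
        return np.nan
    l, r = int(above[0]), int(above[-1])
    xl = float(l) if l == 0 else l - (y[l] - half) / (y[l] - y[l - 1])
    xr = float(r) if r == y.size - 1 else r + (y[r] - half) / (y[r] - y[r + 1])
    return xr - xl


# ---------------------------------------------------------------------------
# PSF correction
# ---------------------------------------------------------------------------


def _blurred_box(x: np.ndarray, center: float, width: float, sigma: float) -> np.ndarray:
    s = np.sqrt(2.0) * sigma
    return 0.5 * (erf((x - center + width / 2) / s) - erf((x - center - width / 2) / s))


@lru_cache(maxsize=32)
def fwhm_calibration(model: str, psf_sigma_px: float) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Forward-model calibration curve: true box width -> fitted FWHM.

    The clearance signal is (ideally) a top-hat of the cleared width
    convolved with a Gaussian PSF.  Fitting such a profile with a
    Gaussian under- or over-estimates the top-hat width depending on the
    width/PSF ratio, and quadrature subtraction of the PSF FWHM does not
    repair this (it over-corrects flat-topped profiles).  Instead we
    tabulate, for the *same fitter the pipeline uses*, the fitted FWHM of
    noiseless blurred boxes over a grid of true widths; inverting this
    monotone map yields an estimate that is exact on noiseless profiles
    at any width.

    Returns ``(widths, fitted_fwhms)`` as tuples (cached; hashable).
    """
    widths = np.concatenate([np.linspace(0.25, 6, 24), np.linspace(6.5, 60, 108)])
    span = int(widths.max() * 1.6) + 24
    x = np.arange(span, dtype=float)
    center = span / 2.0
    if model == "halfmax":
        fitted = np.array(
            [halfmax_width(_blurred_box(x, center, w, psf_sigma_px)) for w in widths]
        )
        ok = np.isfinite(fitted)
        widths, fitted = widths[ok], fitted[ok]
        fitted = np.maximum.accumulate(fitted)
        fitted += np.arange(fitted.size) * 1e-9
        return tuple(widths), tuple(fitted)
    fitter = _FITTERS[model]
    fitted = np.empty_like(widths)
    for i, w in enumerate(widths):
        profile = _blurred_box(x, center, w, psf_sigma_px)
        fit = fitter(profile)
        if fit.converged:
            # refit in the same cropped window build_trace uses, so the
            # calibration matches the pipeline's own measurement
            half = max(10.5, 1.5 * fit.fwhm_px)
            lo = int(max(0, np.floor(fit.center_px - half)))
            hi = int(min(span, np.ceil(fit.center_px + half)))
            if hi - lo >= 7:
                refit = fitter(profile[lo:hi])
                if refit.converged:
                    fit = refit
        fitted[i] = fit.fwhm_px if fit.converged else np.nan
    ok = np.isfinite(fitted)
    widths, fitted = widths[ok], fitted[ok]
    # enforce strict monotonicity so the inverse is well defined
    fitted = np.maximum.accumulate(fitted)
    fitted += np.arange(fitted.size) * 1e-9
    return tuple(widths), tuple(fitted)


def correct_fwhm(
    fwhm_px: float | np.ndarray,
    psf_sigma_px: float,
    method: str = "none",
    model: str = "gaussian",
):
    """Convert an as-fitted FWHM into an estimate of the true cleared width.

    ``method='none'`` returns the input; ``'quadrature'`` subtracts the
    PSF FWHM in quadrature (floor at zero); ``'model'`` inverts the
    blurred-box forward map from :func:`fwhm_calibration` (recommended
    when the PSF sigma is known).
    """
    f = np.asarray(fwhm_px, dtype=float)
    if method == "none":
        out = f
    elif method == "quadrature":
        psf = FWHM_PER_SIGMA * psf_sigma_px
        out = np.sqrt(np.clip(f**2 - psf**2, 0.0, None))
    elif method == "model":
        w_grid, f_grid = fwhm_calibration(model, round(float(psf_sigma_px), 4))
        out = np.interp(f, f_grid, w_grid, left=0.0)
        top_f, top_w = f_grid[-1], w_grid[-1]
        big = f > top_f
        if np.any(big):  # extrapolate linearly with unit slope past the table
            out = np.where(big, top_w + (f - top_f), out)
    else:
        raise ValueError(f"unknown psf correction {method!r}")
    return float(out) if np.isscalar(fwhm_px) else out


# ---------------------------------------------------------------------------
# trace building
# ---------------------------------------------------------------------------


@dataclass
class ClearanceTrace:
    """Per-molecule FWHM(t) series with fit diagnostics.

    ``df`` has one row per frame with columns ``frame, time_s, center_px,
    fwhm_px_fit, fwhm_px, fwhm_nt, left_edge_px, right_edge_px,
    amplitude, baseline, r2, converged``.  ``fwhm_px`` is PSF-corrected
    according to ``psf_correction`` (equal to ``fwhm_px_fit`` for
    ``'none'``); ``fwhm_nt = fwhm_px * nt_per_px``.  Frames whose fit did
    not converge carry NaN geometry and are treated as missing.
    """

    molecule_id: str
    channel: str
    model: str
    df: pd.DataFrame
    nt_per_px: float
    frame_interval_s: float
    psf_correction: str = "none"
    usable: bool = True
    profiles: np.ndarray | None = None  # (frame, roi column) raw profiles

    @classmethod
    def from_series(
        cls,
        fwhm_nt: np.ndarray,
        frame_interval_s: float,
        nt_per_px: float,
        molecule_id: str = "synthetic",
        center_px: np.ndarray | None = None,
    ) -> "ClearanceTrace":
        """Build a trace directly from an FWHM series (synthetic inputs)."""
        fwhm_nt = np.asarray(fwhm_nt, dtype=float)
        n = fwhm_nt.size
        frames = np.arange(n)
        fwhm_px = fwhm_nt / nt_per_px
        center = np.asarray(center_px, float) if center_px is not None else np.full(n, np.nan)
        left = center - fwhm_px / 2.0
        df = pd.DataFrame(
            {
                "frame": frames,
                "time_s": frames * frame_interval_s,
                "center_px": center,
                "fwhm_px_fit": fwhm_px,
                "fwhm_px": fwhm_px,
                "fwhm_nt": fwhm_nt,
                "left_edge_px": left,
                "right_edge_px": left + fwhm_px,
                "amplitude": np.nan,
                "baseline": np.nan,
                "r2": np.nan,
                "converged": np.isfinite(fwhm_nt),
            }
        )
        return cls(molecule_id, "synthetic", "synthetic", df, nt_per_px, frame_interval_s)

    @property
    def n_frames(self) -> int:
        return len(self.df)

    def filled_fwhm_nt(self) -> np.ndarray:
        """FWHM(t) in nt with missing frames imputed.

        Leading missing frames (typically signal below the detection
        floor before clearance starts) are set to zero; interior gaps are
        linearly interpolated; trailing gaps hold the last observation.
        """
        y = self.df["fwhm_nt"].to_numpy(dtype=float).copy()
        ok = np.isfinite(y)
        if not ok.any():
            return np.zeros_like(y)
        first = int(np.argmax(ok))
        y[:first] = 0.0
        idx = np.arange(y.size)
        y[first:] = np.interp(idx[first:], idx[ok], y[ok])
        return y


#: widths below this are PSF-dominated in the fitted FWHM
_RESOLVED_PX = 2.0
_AREA_REPLACE_PX = 3.0


def _rescale_subresolution_widths(df: pd.DataFrame, model: str) -> None:
    """Replace PSF-dominated widths by flux-anchored estimates, in place.

    Below roughly two pixels the fitted FWHM of a blurred box saturates
    at the PSF width and its inverse becomes ill-conditioned — but the
    fit's *area* (amplitude x width) remains exactly proportional to the
    cleared width, because convolution conserves flux.  The
    proportionality (photons per pixel of clearance) is calibrated per
    trace as the median area-to-width ratio over frames with resolved
    widths, and sub-resolution frames are then read out as area divided
    by that ratio.
    """
    conv = df["converged"].to_numpy(dtype=bool)
    fit_fwhm = df["fwhm_px_fit"].to_numpy(dtype=float)
    amp = df["amplitude"].to_numpy(dtype=float)
    if model == "gaussian":
        area = amp * (fit_fwhm / FWHM_PER_SIGMA) * np.sqrt(2.0 * np.pi)
    else:
        area = amp * fit_fwhm
    w = df["fwhm_px"].to_numpy(dtype=float)
    resolved = conv & (w >= _RESOLVED_PX) & (area > 0)
    if resolved.sum() < 3:
        return
    gain = float(np.median(area[resolved] / w[resolved]))
    if gain <= 0:
        return
    small = conv & (w < _AREA_REPLACE_PX)
    w[small] = np.clip(area[small] / gain, 0.0, None)
    df["fwhm_px"] = w


def _area_backfill(df, stack, roi: MoleculeROI, channel: str, psf_sigma_px: float) -> None:
    """Uniform flux-calibrated width reads for every event frame, in place.

    Because convolution conserves flux, the windowed intensity sum
    around the (localized) event is exactly proportional to the cleared
    width at *any* width, with no detection threshold and no PSF
    nonlinearity; using one estimator for all frames also avoids the
    selection bias of switching estimators on a per-frame noisy width.
    The photons-per-pixel gain is calibrated per trace as a ratio of
    totals over the resolved frames (robust to symmetric width noise in
    the denominator, and free of per-frame selection effects).

    Previously-undetected frames (chiefly sub-detection onset frames)
    borrow the nearest localized center and are flagged ``area_read``
    (excluded from edge and polarity analysis).  Reads may come out
    slightly negative under noise; they are left unclipped so the
    downstream kinetic fit stays unbiased.
    """
    conv = df["converged"].to_numpy(dtype=bool)
    if not conv.any():
        return
    centers = df["center_px"].to_numpy(dtype=float)
    widths = df["fwhm_px"].to_numpy(dtype=float)
    conv_idx = np.nonzero(conv)[0]

    def window(j):
        half = 1.5 * max(widths[j], 2.0) + 5.0
        lo = int(max(0, np.floor(centers[j] - half)))
        hi = int(min(roi.length_px, np.ceil(centers[j] + half)))
        return lo, hi

    resolved = [j for j in conv_idx if widths[j] >= _RESOLVED_PX]
    if len(resolved) < 3:
        return
    sum_area = sum_w = 0.0
    for j in resolved:
        lo, hi = window(j)
        sum_area += extract_profile(stack, roi, int(df.at[j, "frame"]), channel)[lo:hi].sum()
        sum_w += widths[j]
    if sum_w <= 0 or sum_area <= 0:
        return
    gain = sum_area / sum_w

    for f in range(len(df)):
        own_fit = conv[f] and np.isfinite(centers[f])
        j = f if own_fit else int(conv_idx[np.argmin(np.abs(conv_idx - f))])
        lo, hi = window(j)
        if hi - lo < 5:
            continue
        area = extract_profile(stack, roi, int(df.at[f, "frame"]), channel)[lo:hi].sum()
        df.at[f, "fwhm_px"] = area / gain
        if not own_fit:
            df.at[f, "center_px"] = centers[j]
            df.at[f, "converged"] = True
            df.at[f, "area_read"] = True


def build_trace(
    stack: KymographStack,
    roi: MoleculeROI,
    channel: str = "magenta",
    model: str = "gaussian",
    psf_correction: str = "none",
    psf_sigma_px: float | None = None,
) -> ClearanceTrace:
    """Fit every frame of one molecule and assemble a :class:`ClearanceTrace`.

    After the first converged frame the fit window is re-centered on the
    previous frame's center with a width of ``max(21 px, 3x previous
    FWHM)``, following the convention that the ROI length tracks the
    extent of the clearance.  Non-converged frames are carried as
    missing.  A trace in which more than half of the frames *after the
    first detection* fail to converge is flagged unusable.
    """
    if model not in _FITTERS:
        raise ValueError(f"unknown model {model!r}")
    if psf_correction != "none" and psf_sigma_px is None:
        psf_sigma_px = float(stack.meta.get("psf_sigma_px", np.nan))
        if not np.isfinite(psf_sigma_px):
            raise ValueError("psf correction requested but psf_sigma_px unknown")
    fitter = _FITTERS[model]

    rows = []
    profiles = np.empty((stack.n_frames, roi.length_px))
    prev_center: float | None = None
    prev_fwhm: float | None = None
    missed = 0
    length = roi.length_px
    for frame in range(stack.n_frames):
        profile = extract_profile(stack, roi, frame, channel)
        profiles[frame] = profile
        lo = 0
        fit = None
        if prev_center is not None and prev_fwhm is not None:
            half = max(10.5, 1.5 * prev_fwhm)
            wlo = int(max(0, np.floor(prev_center - half)))
            whi = int(min(length, np.ceil(prev_center + half)))
            if whi - wlo >= 7:
                fit = fitter(profile[wlo:whi], frame)
                lo = wlo
        if fit is None or not fit.converged:
            # (re)acquisition over the full molecule: demand stronger
            # evidence than frame-to-frame tracking, so noise bumps do
            # not hijack the fit window before the signal appears
            full = fitter(profile, frame, min_amp_sd=_ACQUIRE_SD)
            if full.converged:
                fit, lo = full, 0
            elif fit is None:
                fit = full
        if fit.converged:
            center = fit.center_px + lo
            prev_center, prev_fwhm = center, fit.fwhm_px
            missed = 0
        else:
            center = np.nan
            missed += 1
            if missed >= 2:  # stale window: force full re-acquisition
                prev_center = prev_fwhm = None
        rows.append(
            {
                "frame": frame,
                "time_s": frame * stack.frame_interval_s,
                "center_px": center,
                "fwhm_px_fit": fit.fwhm_px,
                "amplitude": fit.amplitude,
                "baseline": fit.baseline,
                "r2": fit.r_squared,
                "converged": fit.converged,
            }
        )

    df = pd.DataFrame(rows)
    if psf_sigma_px is not None:
        df.attrs["psf_sigma_px"] = float(psf_sigma_px)
    df["fwhm_px"] = correct_fwhm(
        df["fwhm_px_fit"].to_numpy(), psf_sigma_px or 0.0, psf_correction, model
    )
    df["area_read"] = False
    conv_fit = df["converged"].to_numpy(dtype=bool).copy()
    if psf_correction == "model":
        _rescale_subresolution_widths(df, model)
        _area_backfill(df, stack, roi, channel, psf_sigma_px or 1.3)
    df["fwhm_nt"] = df["fwhm_px"] * stack.nt_per_px
    df["left_edge_px"] = df["center_px"] - df["fwhm_px"] / 2.0
    df["right_edge_px"] = df["center_px"] + df["fwhm_px"] / 2.0

    if conv_fit.any():
        first = int(np.argmax(conv_fit))
        usable = conv_fit[first:].mean() > 0.5
    else:
        usable = False
    return ClearanceTrace(
        roi.molecule_id,
        channel,
        model,
        df,
        stack.nt_per_px,
        stack.frame_interval_s,
        psf_correction,
        usable,
        profiles,
    )
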