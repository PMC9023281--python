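"""Per-motor kinetics from clearance traces.

Turns an FWHM(t) series into the quantities the assay reports: when the
motor was moving, how fast (velocity = slope of the cleared extent over
the rising phase), how far (processivity = terminal plateau extent), and
in which direction (which edge of the cleared region moves).  Population
summaries are medians with interquartile ranges.

Censoring: a motor still translocating when the movie ends gives only a
lower bound on its processivity, as does a front that runs into the 5'
barrier (``boundary_limited`` — its extent is clipped by the tether
geometry rather than by the motor itself).  Population processivity
quartiles treat both as right-censored observations via Kaplan-Meier;
censored events keep their velocity, boundary-limited ones do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kymo import ClearanceTrace

__all__ = [
    "ActivePhase",
    "MotorEvent",
    "PopulationSummary",
    "segment_active_phase",
    "estimate_velocity",
    "estimate_processivity",
    "classify_polarity",
    "extract_event",
    "population_summary",
    "summarize_events",
    "events_to_frame",
]


@dataclass
class ActivePhase:
    """Rising-phase window of a clearance trace (frame indices, inclusive).

    ``slope_nt_per_frame`` and ``plateau_level_nt`` carry the continuous
    ramp fit's slope and attained level; they pool all frames of the
    trace and are the preferred kinetic read-outs.
    """

    start_frame: int | None
    end_frame: int | None
    censored: bool = False
    slope_nt_per_frame: float = np.nan
    plateau_level_nt: float = np.nan
    start_frame_f: float = np.nan  # sub-frame refined changepoints
    end_frame_f: float = np.nan
    resid_sd_nt: float = np.nan  # per-frame scatter about the fitted ramp

    @property
    def moving(self) -> bool:
        return self.start_frame is not None


@dataclass
class MotorEvent:
    """One clearance event's kinetic read-out."""

    molecule_id: str
    velocity_nt_s: float
    processivity_knt: float
    polarity: str  # '3to5' | '5to3' | 'ambiguous'
    censored: bool
    boundary_limited: bool = False
    velocity_clipped: bool = False
    velocity_measurable: bool = True
    start_frame: int | None = None
    end_frame: int | None = None
    usable: bool = True
    diagnostics: dict = field(default_factory=dict)


@dataclass
class PopulationSummary:
    statistic: str
    median: float
    iqr: tuple[float, float]
    n: int
    units: str


# ---------------------------------------------------------------------------
# changepoint segmentation
# ---------------------------------------------------------------------------


def _wprefix(y: np.ndarray, m: np.ndarray):
    """Prefix sums of the masked series (weight 0/1 per frame)."""
    t = np.arange(y.size, dtype=float)
    z = np.zeros(1)

    def ps(v):
        return np.concatenate([z, np.cumsum(v)])

    return {
        "W": ps(m),
        "Y": ps(m * y),
        "YY": ps(m * y * y),
        "T": ps(m * t),
        "TT": ps(m * t * t),
        "TY": ps(m * t * y),
    }


def _ramp_sse(p, n: int, c1: int, c2s: np.ndarray):
    """SSE and slope of the continuous flat-rise-flat model (masked).

    The model is ``y(t) = b0 + v * clip(t - c1, 0, c2 - c1)``: flat at
    ``b0`` before ``c1``, rising at ``v`` between the changepoints, flat
    at the attained level after ``c2``.  Linear in ``(b0, v)`` given the
    changepoints, so each candidate pair is a closed-form weighted 2x2
    least-squares solve assembled from prefix sums — O(1) per pair,
    vectorized over an array of ``c2`` candidates.  Masked frames
    (weight 0) contribute nothing.
    """
    c2s = np.asarray(c2s)
    plateau = (c2s - c1).astype(float)
    wb = p["W"][c2s] - p["W"][c1]
    st_b = p["T"][c2s] - p["T"][c1]
    st2_b = p["TT"][c2s] - p["TT"][c1]
    sy_b = p["Y"][c2s] - p["Y"][c1]
    sty_b = p["TY"][c2s] - p["TY"][c1]
    wc = p["W"][n] - p["W"][c2s]
    sy_c = p["Y"][n] - p["Y"][c2s]

    syy = p["YY"][n]
    sr2 = (st2_b - 2 * c1 * st_b + c1 * c1 * wb) + plateau**2 * wc
    sry = (sty_b - c1 * sy_b) + plateau * sy_c

    # the pre-event baseline of a background-subtracted FWHM series is
    # structurally zero, so the ramp is fit through the origin: one free
    # parameter (the slope) given the changepoints
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(sr2 > 1e-9, sry / np.where(sr2 > 1e-9, sr2, 1.0), 0.0)
    sse = syy - v * sry
    return np.clip(sse, 0.0, None), v


def _ramp_sse_cont(y: np.ndarray, m: np.ndarray, c1: float, c2: float):
    """Masked SSE and slope of the zero-baseline ramp at float changepoints."""
    t = np.arange(y.size, dtype=float)
    r = np.clip(t - c1, 0.0, max(c2 - c1, 1e-9))
    sr2 = (m * r * r).sum()
    sry = (m * r * y).sum()
    if sr2 <= 1e-9 or m.sum() < 4:
        return np.inf, 0.0
    v = sry / sr2
    sse = float((m * (y - v * r) ** 2).sum())
    return sse, float(v)


def _refine_changepoints(
    y: np.ndarray, m: np.ndarray, c1: int, c2: int, rise_to_end: bool, step: float = 0.1
) -> tuple[float, float]:
    n = y.size
    c1g = np.arange(max(0.0, c1 - 1.0), min(n - 2.0, c1 + 1.0) + 1e-9, step)
    c2g = (
        np.array([float(n - 1)])
        if rise_to_end
        else np.arange(max(c1 - 1.0, c2 - 1.0), min(n - 1.0, c2 + 1.0) + 1e-9, step)
    )
    best = (np.inf, float(c1), float(c2))
    for a in c1g:
        for b in c2g:
            if b - a < 0.5:
                continue
            sse, v = _ramp_sse_cont(y, m, a, b)
            if v > 0 and sse < best[0]:
                best = (sse, float(a), float(b))
    return best[1], best[2]


_MIN_RISE = 2  # frames between the changepoints
_MIN_TAIL = 2  # frames of terminal plateau


def _series_and_mask(trace, gap: int = 1):
    """Imputed FWHM series plus fit weights.

    Converged frames (including flux-calibrated area reads) enter with
    their measured widths; frames before the first covered frame are
    true zeros, except a ``gap``-frame buffer just before it, during
    which the motor may already be moving below every readout — those
    are masked out of the ramp fit rather than pinned at zero, which
    would otherwise delay the apparent onset and steepen the slope.
    Interior and trailing non-converged frames are masked as missing.
    """
    if isinstance(trace, ClearanceTrace):
        y = trace.df["fwhm_nt"].to_numpy(dtype=float).copy()
        conv = trace.df["converged"].to_numpy(dtype=bool)
        m = conv.astype(float)
        y[~conv] = 0.0
        if conv.any():
            first = int(np.argmax(conv))
            m[: max(first - gap, 0)] = 1.0  # confidently pre-event zeros
            y[: max(first - gap, 0)] = 0.0
    else:
        y = np.asarray(trace, dtype=float)
        m = np.isfinite(y).astype(float)
        y = np.where(np.isfinite(y), y, 0.0)
    return y, m


def _fit_phase(y: np.ndarray, m: np.ndarray) -> ActivePhase:
    n = y.size
    p = _wprefix(y, m)
    N = p["W"][n]
    if N < 4:
        return ActivePhase(None, None, False)
    sy, syy = p["Y"][n], p["YY"][n]
    sse_flat = float(syy - sy * sy / N)

    best2 = (np.inf, 0)  # rise continues to the last frame
    best3 = (np.inf, 0, n - 1)
    for c1 in range(0, n - _MIN_RISE):
        sse2, v2 = _ramp_sse(p, n, c1, np.array([n - 1]))
        if v2[0] > 0 and sse2[0] < best2[0]:
            best2 = (float(sse2[0]), c1)
        c2s = np.arange(c1 + _MIN_RISE, n - _MIN_TAIL)
        if c2s.size:
            sse3, v3 = _ramp_sse(p, n, c1, c2s)
            valid = v3 > 0
            if valid.any():
                j = int(np.argmin(np.where(valid, sse3, np.inf)))
                if sse3[j] < best3[0]:
                    best3 = (float(sse3[j]), c1, int(c2s[j]))

    eps = 1e-12 + 1e-9 * max(sse_flat, 1.0)

    def bic(sse: float, k: int) -> float:
        return N * np.log(max(sse, eps) / N) + k * np.log(N)

    candidates = [(bic(sse_flat, 1), ActivePhase(None, None, False))]
    if np.isfinite(best2[0]):
        candidates.append((bic(best2[0], 2), ActivePhase(best2[1], n - 1, True)))
    if np.isfinite(best3[0]):
        candidates.append((bic(best3[0], 3), ActivePhase(best3[1], best3[2], False)))
    phase = min(candidates, key=lambda c: c[0])[1]
    if phase.moving:
        # sub-frame changepoint refinement: the true knees rarely fall on
        # frame times, and with rises only a few frames long the integer
        # quantization alone biases the slope by >10%
        c1, c2 = _refine_changepoints(
            y, m, phase.start_frame, phase.end_frame, rise_to_end=phase.censored
        )
        sse_f, vv = _ramp_sse_cont(y, m, c1, c2)
        phase.resid_sd_nt = float(np.sqrt(sse_f / max(m.sum() - 3.0, 1.0)))
        phase.start_frame = int(round(c1))
        phase.end_frame = int(round(c2)) if not phase.censored else n - 1
        phase.start_frame_f = float(c1)
        phase.end_frame_f = float(c2) if not phase.censored else float(n - 1)
        phase.slope_nt_per_frame = vv
        phase.plateau_level_nt = vv * (c2 - c1)
    return phase


def segment_active_phase(trace: ClearanceTrace | np.ndarray) -> ActivePhase:
    """Two-changepoint piecewise-linear (flat-rise-flat) segmentation.

    Fits a *continuous* flat-rise-flat ramp (flat baseline, linear rise
    between changepoints ``c1 < c2``, flat plateau at the attained
    level) to the FWHM(t) series by exhaustive SSE search over
    changepoint pairs, and selects between flat (no event), flat-rise to
    the movie end (censored), and flat-rise-flat by BIC.  Continuity is
    what makes the short rising phase identifiable against per-frame
    FWHM noise.  Non-converged frames are masked; the onset blind gap
    (frames in which the motor moves below the detection floor) is sized
    from the fitted slope itself in a second pass.
    """
    n = len(trace.df) if isinstance(trace, ClearanceTrace) else np.asarray(trace).size
    if n < 5:
        raise ValueError("trace shorter than 5 frames cannot be segmented")
    y, m = _series_and_mask(trace)
    return _fit_phase(y, m)


# ---------------------------------------------------------------------------
# per-event estimates
# ---------------------------------------------------------------------------


def _phase_points(trace: ClearanceTrace, phase: ActivePhase, col: str = "fwhm_nt"):
    """(time_s, values) of converged frames inside the rising window."""
    df = trace.df
    sel = (
        (df["frame"] >= phase.start_frame)
        & (df["frame"] <= phase.end_frame)
        & df["converged"]
    )
    sub = df.loc[sel]
    return sub["time_s"].to_numpy(dtype=float), sub[col].to_numpy(dtype=float)


def estimate_velocity(trace: ClearanceTrace, phase: ActivePhase) -> float:
    """Front velocity in nt/s: least-squares slope of FWHM_nt over the rise.

    The cleared region expands one-sidedly, so the FWHM growth rate *is*
    the front speed.  The slope comes from the continuous ramp fit of
    :func:`segment_active_phase`, which constrains the rising line to
    join the baseline and plateau levels — with rising phases only a
    handful of frames long this pools far more data than a free line
    through the rise window alone.  Negative slopes are clipped to zero
    (flagged via :func:`extract_event`).
    """
    if not phase.moving:
        return 0.0
    if np.isfinite(phase.slope_nt_per_frame):
        return max(phase.slope_nt_per_frame / trace.frame_interval_s, 0.0)
    t, y = _phase_points(trace, phase)
    if t.size < 3:
        raise ValueError("rising phase has fewer than 3 frames")
    slope = float(np.polyfit(t, y, 1)[0])
    if not np.isfinite(slope):
        raise ValueError("non-finite velocity slope")
    return max(slope, 0.0)


def estimate_processivity(trace: ClearanceTrace, phase: ActivePhase) -> float:
    """Processivity in knt: mean terminal-plateau FWHM_nt.

    For censored events (no terminal plateau) the last observed FWHM is
    returned, which is a lower bound.
    """
    if not phase.moving:
        return 0.0
    df = trace.df
    obs = df.loc[df["converged"], "fwhm_nt"]
    if phase.censored:
        return float(obs.iloc[-1]) / 1000.0 if len(obs) else 0.0
    if np.isfinite(phase.plateau_level_nt):
        return float(phase.plateau_level_nt) / 1000.0
    tail = df.loc[(df["frame"] > phase.end_frame) & df["converged"], "fwhm_nt"]
    if len(tail) == 0:
        return float(obs.iloc[-1]) / 1000.0 if len(obs) else 0.0
    return float(tail.mean()) / 1000.0


_MIN_EDGE_WIDTH_PX = 2.0  # edges are undefined while the width is sub-PSF


def classify_polarity(trace: ClearanceTrace, phase: ActivePhase) -> str:
    """Which edge of the cleared region moves during the event.

    When the raw per-frame profiles are available (traces built by
    :func:`~kymoclear.kymo.build_trace`), polarity is decided by a
    profile-level hypothesis test: the event's frames are refit jointly
    with a PSF-blurred box whose width follows the measured FWHM series
    while one anchor is shared across frames — the 3' edge (box grows
    toward the barrier: 3'->5'), the 5' edge (box grows away: 5'->3'),
    or the center (symmetric growth).  The hypothesis with the lowest
    summed squared error wins if it beats the runner-up by ~2 sigma;
    otherwise 'ambiguous'.  This uses every photon of the rising
    frames, where the three hypotheses predict box positions differing
    by up to half the final width.

    For synthetic traces without profiles, a center-shift test is used:
    one-sided growth drags the fitted center toward the moving edge by
    half the width increment.
    """
    if not phase.moving:
        return "ambiguous"
    if trace.profiles is not None:
        return _polarity_from_profiles(trace, phase)
    return _polarity_from_centers(trace, phase)


def _polarity_from_profiles(trace: ClearanceTrace, phase: ActivePhase) -> str:
    from scipy.special import erf

    df = trace.df
    prof = trace.profiles
    n_cols = prof.shape[1]
    conv = df["converged"].to_numpy(dtype=bool)
    w_px = df["fwhm_px"].to_numpy(dtype=float)
    frames = df["frame"].to_numpy()

    lo_f, hi_f = phase.start_frame, min(phase.end_frame + 8, len(df) - 1)
    use = conv & (frames >= lo_f) & (frames <= hi_f) & np.isfinite(w_px) & (w_px > 0.3)
    idx = np.nonzero(use)[0]
    if idx.size < 3:
        return "ambiguous"
    w_plat = (
        phase.plateau_level_nt / trace.nt_per_px
        if np.isfinite(phase.plateau_level_nt) and phase.plateau_level_nt > 0
        else float(np.nanmax(w_px[idx]))
    )
    # drive the model with the smooth ramp widths, not the noisy
    # per-frame measurements: model misfit then reflects anchor choice
    # plus photon noise only
    slope_px = (
        phase.slope_nt_per_frame / trace.nt_per_px
        if np.isfinite(phase.slope_nt_per_frame)
        else w_plat / max(phase.end_frame - phase.start_frame, 1)
    )
    c1f = phase.start_frame_f if np.isfinite(phase.start_frame_f) else phase.start_frame
    w_ramp = np.clip((frames - c1f) * slope_px, 0.0, w_plat)
    use = use & (w_ramp > 0.3)
    idx = np.nonzero(use)[0]
    if idx.size < 3:
        return "ambiguous"
    centers = df["center_px"].to_numpy(dtype=float)
    c_ref = float(np.nanmedian(centers[idx]))
    if not np.isfinite(c_ref):
        return "ambiguous"

    sigma = float(trace.df.attrs.get("psf_sigma_px", 1.3))
    x = np.arange(n_cols, dtype=float)
    s2 = np.sqrt(2.0) * sigma

    # flux gain per pixel of cleared width, from the widest frames
    widest = idx[np.argsort(w_ramp[idx])[-5:]]
    gain = float(np.median([prof[j].sum() / w_ramp[j] for j in widest if w_ramp[j] > 0]))
    if not np.isfinite(gain):
        return "ambiguous"
    if gain <= 0:
        return "ambiguous"

    anchors = np.arange(max(0.0, c_ref - w_plat - 3), min(n_cols - 1.0, c_ref + w_plat + 3), 0.5)

    def sse_for(mode: str) -> float:
        # small onset offsets absorb residual changepoint error so it
        # cannot masquerade as an anchor preference
        best = np.inf
        for delta in (-0.6, -0.3, 0.0, 0.3, 0.6):
            w_d = np.clip((frames - c1f - delta) * slope_px, 0.0, w_plat)
            for a in anchors:
                total = 0.0
                for j in idx:
                    w = max(w_d[j], 0.2)
                    if mode == "right":  # fixed 3' edge, growth toward barrier
                        e1, e2 = a - w, a
                    elif mode == "left":
                        e1, e2 = a, a + w
                    else:
                        e1, e2 = a - w / 2, a + w / 2
                    model = 0.5 * gain * (erf((x - e1) / s2) - erf((x - e2) / s2))
                    total += float(((prof[j] - model) ** 2).sum())
                    if total >= best:
                        break
                best = min(best, total)
        return best

    sses = {m: sse_for(m) for m in ("right", "left", "center")}
    order = sorted(sses, key=sses.get)
    n_pts = idx.size * n_cols
    noise_var = max(sses[order[0]] / max(n_pts - idx.size - 1, 1), 1e-12)
    margin = sses[order[1]] - sses[order[0]]
    if margin < 4.0 * noise_var:
        return "ambiguous"
    return {"right": "3to5", "left": "5to3", "center": "ambiguous"}[order[0]]


def _polarity_from_centers(trace: ClearanceTrace, phase: ActivePhase) -> str:
    df = trace.df
    sel = (
        (df["frame"] >= phase.start_frame)
        & df["converged"]
        & ~df.get("area_read", False)
        & np.isfinite(df["center_px"])
        & np.isfinite(df["fwhm_px"])
    )
    sub = df.loc[sel]
    if len(sub) < 5:
        return "ambiguous"
    c = sub["center_px"].to_numpy(dtype=float)
    w = sub["fwhm_px"].to_numpy(dtype=float)
    frames = sub["frame"].to_numpy()
    keep = np.abs(c - np.median(c)) < 10.0  # spurious off-event fits
    c, w, frames = c[keep], w[keep], frames[keep]
    if c.size < 5:
        return "ambiguous"
    rise = frames < phase.end_frame
    plat = frames > phase.end_frame
    if rise.sum() < 1 or plat.sum() < 3:
        return "ambiguous"
    dw = float(w[plat].mean() - w[rise].mean())
    if dw < 2.0:
        return "ambiguous"
    sd_c = float(np.std(c[plat], ddof=1))
    beta = float(c[plat].mean() - c[rise].mean()) / dw
    se = sd_c * np.sqrt(1.0 / rise.sum() + 1.0 / plat.sum()) / dw
    if beta + 2.0 * se < -0.15:
        return "3to5"
    if beta - 2.0 * se > 0.15:
        return "5to3"
    return "ambiguous"


def extract_event(
    trace: ClearanceTrace, barrier_margin_px: float = 2.0
) -> MotorEvent:
    """Segment a trace and package velocity, processivity, and polarity.

    ``boundary_limited`` is set when the cleared region's 5' edge comes
    within ``barrier_margin_px`` of the barrier during or after the rise
    — the realized extent is then clipped by the tether geometry and the
    event is excluded from processivity summaries (like censoring).
    """
    phase = segment_active_phase(trace)
    if not phase.moving:
        return MotorEvent(trace.molecule_id, 0.0, 0.0, "ambiguous", False, usable=trace.usable)
    t, y = _phase_points(trace, phase)
    raw_slope = float(np.polyfit(t, y, 1)[0]) if t.size >= 3 else np.nan
    velocity = estimate_velocity(trace, phase)
    processivity = estimate_processivity(trace, phase)
    polarity = classify_polarity(trace, phase)
    # a rise can only be timed when the attained level clears the
    # per-frame width noise; below that the fitted duration, and hence
    # the velocity, is unconstrained
    v_ok = bool(
        np.isfinite(phase.plateau_level_nt)
        and phase.plateau_level_nt >= 4.0 * phase.resid_sd_nt
    )
    df = trace.df
    tail_start = phase.end_frame if not phase.censored else phase.start_frame
    post = df.loc[
        (df["frame"] >= tail_start) & df["converged"] & ~df.get("area_read", False),
        "left_edge_px",
    ]
    boundary = bool(len(post) >= 1 and post.mean() < barrier_margin_px)
    return MotorEvent(
        molecule_id=trace.molecule_id,
        velocity_nt_s=velocity,
        processivity_knt=processivity,
        polarity=polarity,
        censored=phase.censored,
        boundary_limited=boundary,
        velocity_clipped=bool(np.isfinite(raw_slope) and raw_slope < 0),
        velocity_measurable=v_ok,
        start_frame=phase.start_frame,
        end_frame=phase.end_frame,
        usable=trace.usable,
        diagnostics={"raw_slope_nt_s": raw_slope, "n_rise_points": int(t.size)},
    )


# ---------------------------------------------------------------------------
# population statistics
# ---------------------------------------------------------------------------


def population_summary(values, statistic: str, units: str = "") -> PopulationSummary:
    """Median and linearly interpolated (type-7) IQR of a sample."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("population_summary of an empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return PopulationSummary(statistic, float(med), (float(q1), float(q3)), int(v.size), units)


def events_to_frame(events: list[MotorEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "molecule_id": e.molecule_id,
                "velocity_nt_s": e.velocity_nt_s,
                "processivity_knt": e.processivity_knt,
                "polarity": e.polarity,
                "censored": e.censored,
                "boundary_limited": e.boundary_limited,
                "velocity_measurable": e.velocity_measurable,
                "velocity_clipped": e.velocity_clipped,
                "usable": e.usable,
            }
            for e in events
        ]
    )


def _km_quartiles(values: np.ndarray, observed: np.ndarray):
    """Kaplan-Meier median and IQR of right-censored observations.

    A motor still translocating at the movie end, or one whose front ran
    into the 5' tether, yields only a lower bound on its processivity.
    Simply dropping such events biases the median low, because long
    events are preferentially censored; treating them as right-censored
    observations (censoring — movie length, initiation position — is
    independent of the motor's processivity) recovers the population
    quartiles without bias.  Quantiles that the survival curve never
    reaches fall back on the largest observation.
    """
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(values, event_observed=observed)
    sf = km.survival_function_
    t = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)

    def quantile(q):
        # linear interpolation between survival steps; stepping to the
        # first time with S <= 1-q would bias the quantile upward by
        # half an inter-event gap
        target = 1.0 - q
        below = np.nonzero(surv <= target)[0]
        if below.size == 0:
            return float(values.max())
        j = int(below[0])
        if j == 0 or surv[j] == target:
            return float(t[j])
        s0, s1 = surv[j - 1], surv[j]
        return float(t[j - 1] + (t[j] - t[j - 1]) * (s0 - target) / (s0 - s1))

    return quantile(0.25), quantile(0.5), quantile(0.75)


def summarize_events(
    events: list[MotorEvent], include_censored_processivity: bool = False
) -> pd.DataFrame:
    """Population summaries over usable, moving events.

    Velocity medians include censored events (speed is measured on the
    rise) but exclude boundary-limited ones — their clearance is
    squeezed against the 5' tether and spatially truncated before a
    slope can be measured — and events whose rise is too small to time.

    Processivity is an endpoint quantity: censored and boundary-limited
    events contribute as right-censored observations through a
    Kaplan-Meier estimate of the quartiles (see :func:`_km_quartiles`);
    with ``include_censored_processivity`` their point values are pooled
    directly instead.
    """
    moving = [e for e in events if e.usable and e.start_frame is not None]
    vel = [
        e.velocity_nt_s
        for e in moving
        if not e.boundary_limited and e.velocity_measurable
    ]
    rows = []
    if vel:
        s = population_summary(vel, "velocity", "nt/s")
        rows.append(
            {
                "statistic": "velocity",
                "median": s.median,
                "q1": s.iqr[0],
                "q3": s.iqr[1],
                "n": s.n,
                "units": s.units,
            }
        )
    pro = [
        (e.processivity_knt, not (e.censored or e.boundary_limited))
        for e in moving
        if e.processivity_knt > 0
    ]
    if pro:
        values = np.array([p for p, _ in pro])
        observed = np.array([o for _, o in pro])
        if include_censored_processivity or observed.all():
            s = population_summary(values, "processivity", "knt")
            q1, med, q3 = s.iqr[0], s.median, s.iqr[1]
        else:
            q1, med, q3 = _km_quartiles(values, observed)
        rows.append(
            {
                "statistic": "processivity",
                "median": med,
                "q1": q1,
                "q3": q3,
                "n": len(pro),
                "units": "knt",
            }
        )
    return pd.DataFrame(rows)
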