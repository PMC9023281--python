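"""Ensemble binding analysis: EMSA fraction bound, hyperbolic Kd fits,
and dissociation time courses.

The binding model is one-site specific binding without a Hill
coefficient, ``f([P]) = Bmax [P] / (Kd + [P])``, fitted to replicate
means weighted by their SEM.  When the lower 95% bound on Kd exceeds
the highest tested concentration the affinity cannot be resolved within
the titration range and the result is reported as a lower bound
("Kd > max concentration").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "fraction_bound",
    "BindingCurve",
    "fit_hyperbolic",
    "DissociationResult",
    "dissociation_timecourse",
]

log = logging.getLogger(__name__)


def fraction_bound(bound_intensity, free_intensity):
    """EMSA fraction bound, ``f = bound / (bound + free)``.

    Scale-invariant in the lane intensities.  Lanes where both bands are
    zero give NaN (missing).  Negative intensities are rejected.
    """
    b = np.asarray(bound_intensity, dtype=float)
    u = np.asarray(free_intensity, dtype=float)
    if np.any(b < 0) or np.any(u < 0):
        raise ValueError("band intensities must be non-negative")
    total = b + u
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(total > 0, b / np.where(total > 0, total, 1.0), np.nan)
    if np.isscalar(bound_intensity) and np.isscalar(free_intensity):
        return float(f)
    return f


def _hyperbola(c, bmax, kd):
    return bmax * c / (kd + c)


@dataclass
class BindingCurve:
    """Hyperbolic binding fit result.

    ``censored`` marks fits whose lower 95% bound on Kd exceeds the
    maximum tested concentration; ``reported_kd`` then returns that
    lower bound (the "Kd > X nM" convention) instead of the point
    estimate.
    """

    concentrations_nM: np.ndarray
    fraction_bound: np.ndarray  # (replicates, concentrations)
    kd_nM: float = np.nan
    kd_se: float = np.nan
    bmax: float = np.nan
    bmax_se: float = np.nan
    success: bool = False
    censored: bool = False
    message: str = ""
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_replicates(self) -> int:
        return self.fraction_bound.shape[0]

    @property
    def max_concentration_nM(self) -> float:
        return float(np.max(self.concentrations_nM))

    @property
    def kd_lower95(self) -> float:
        return self.kd_nM - 1.96 * self.kd_se

    @property
    def reported_kd(self) -> float:
        """Point estimate, or the lower 95% bound for censored fits."""
        return self.kd_lower95 if self.censored else self.kd_nM

    @property
    def kd_label(self) -> str:
        if not self.success:
            return "n.d."
        if self.censored:
            return f"> {self.max_concentration_nM:g} nM"
        return f"{self.kd_nM:.3g} +/- {self.kd_se:.2g} nM"

    def summary(self) -> str:
        lines = [
            "One-site hyperbolic binding fit",
            "-" * 33,
            f"replicates:        {self.n_replicates}",
            f"concentrations:    {len(self.concentrations_nM)} "
            f"(max {self.max_concentration_nM:g} nM)",
            f"Kd:                {self.kd_label}",
            f"Bmax:              {self.bmax:.3g} +/- {self.bmax_se:.2g}",
            f"converged:         {self.success}",
        ]
        if self.message:
            lines.append(f"note:              {self.message}")
        return "\n".join(lines)


def fit_hyperbolic(concs, f_replicates) -> BindingCurve:
    """Fit ``f = Bmax [P] / (Kd + [P])`` to a titration.

    ``f_replicates`` is (replicates x concentrations) or 1-D.  Replicate
    means are fitted with SEM weights (unweighted when any SEM is zero).
    Initialization: Kd at the concentration nearest half-maximum, Bmax
    at the maximum mean.  Monotone-decreasing data are flagged as a fit
    failure rather than fitted.
    """
    concs = np.asarray(concs, dtype=float)
    reps = np.atleast_2d(np.asarray(f_replicates, dtype=float))
    if reps.shape[1] != concs.size and reps.shape[0] == concs.size:
        reps = reps.T
    if np.unique(concs).size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    result = BindingCurve(concs, reps)

    mean = np.nanmean(reps, axis=0)
    if reps.shape[0] > 1:
        sem = np.nanstd(reps, axis=0, ddof=1) / np.sqrt(reps.shape[0])
    else:
        sem = np.zeros_like(mean)

    if mean[np.argmax(concs)] <= mean[np.argmin(concs)] and np.polyfit(concs, mean, 1)[0] < 0:
        result.message = "fraction bound decreases with concentration; no hyperbolic fit"
        return result

    bmax0 = float(mean.max())
    if bmax0 <= 0:
        result.message = "no binding signal"
        return result
    nonzero = concs > 0
    kd0 = float(concs[nonzero][np.argmin(np.abs(mean[nonzero] - bmax0 / 2.0))])
    sigma = sem if np.all(sem > 0) else None
    try:
        popt, pcov = curve_fit(
            _hyperbola,
            concs,
            mean,
            p0=[bmax0, kd0],
            sigma=sigma,
            bounds=([0.0, 1e-9], [np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        result.message = f"optimizer failure: {exc}"
        return result

    result.bmax, result.kd_nM = (float(v) for v in popt)
    result.bmax_se, result.kd_se = (float(np.sqrt(v)) for v in np.diag(pcov))
    result.residuals = mean - _hyperbola(concs, *popt)
    result.success = True
    result.censored = result.kd_lower95 > result.max_concentration_nM
    return result


@dataclass
class DissociationResult:
    times_min: np.ndarray
    normalized: np.ndarray
    k_off_per_min: float | None = None
    dropped: list = field(default_factory=list)


def dissociation_timecourse(
    times_min, treated, control, fit_k_off: bool = True
) -> DissociationResult:
    """Normalize a dissociation course to its matched control.

    ``normalized(t) = treated(t) / control(t)``; points with a
    non-positive control are dropped with a log entry.  Optionally fits
    ``A exp(-k t)`` for the off rate.
    """
    t = np.asarray(times_min, dtype=float)
    tr = np.asarray(treated, dtype=float)
    co = np.asarray(control, dtype=float)
    if not (t.size == tr.size == co.size):
        raise ValueError("treated and control must share the time axis")
    keep = co > 0
    dropped = list(np.nonzero(~keep)[0])
    for i in dropped:
        log.warning("dropping t=%g min: control value %g <= 0", t[i], co[i])
    t, tr, co = t[keep], tr[keep], co[keep]
    norm = tr / co
    k = None
    if fit_k_off and t.size >= 3:
        pos = norm > 0
        slope = -np.polyfit(t[pos], np.log(norm[pos]), 1)[0] if pos.sum() >= 2 else 0.1
        try:
            popt, _ = curve_fit(
                lambda tt, a, kk: a * np.exp(-kk * tt),
                t,
                norm,
                p0=[1.0, max(slope, 1e-6)],
                maxfev=10000,
            )
            k = float(popt[1])
        except (RuntimeError, ValueError):
            k = None
    return DissociationResult(t, norm, k, dropped)
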