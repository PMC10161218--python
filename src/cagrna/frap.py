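"""FRAP mobile-fraction analysis for RNA foci.

A fluorescence-recovery-after-photobleaching (FRAP) trace is normalized so
the pre-bleach plateau equals 1 (with optional reference-region correction
for acquisition bleaching) and the post-bleach recovery is fit with a single
exponential

    I(t) = I0 + (I_plateau - I0) * (1 - exp(-(t - t_bleach)/tau)).

The mobile fraction is the share of the bleached fluorescence that returns:
f_mobile = (I_plateau - I0) / (1 - I0).  Only f_mobile and the recovery time
tau are reported; no diffusion model is attached to tau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["FRAPTrace", "NormalizedFRAP", "FRAPFit", "normalize_frap", "fit_recovery"]


@dataclass
class FRAPTrace:
    """Raw ROI intensity time series with the bleach event at ``bleach_index``.

    ``bleach_index`` is the index of the first post-bleach sample.
    ``reference_intensity`` (optional) is an unbleached reference region used
    to correct for acquisition bleaching.
    """

    time: np.ndarray
    roi_intensity: np.ndarray
    bleach_index: int
    reference_intensity: np.ndarray | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.roi_intensity = np.asarray(self.roi_intensity, dtype=float)
        if self.reference_intensity is not None:
            self.reference_intensity = np.asarray(self.reference_intensity, dtype=float)
            if self.reference_intensity.shape != self.roi_intensity.shape:
                raise ValueError("reference series must match ROI series length")
            if np.any(self.reference_intensity <= 0):
                raise ValueError("reference intensities must be positive")
        if self.time.shape != self.roi_intensity.shape:
            raise ValueError("time and intensity must have matching shapes")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.roi_intensity <= 0):
            raise ValueError("intensities must be positive")
        if self.bleach_index < 3:
            raise ValueError("need >= 3 pre-bleach samples")
        if self.time.size - self.bleach_index < 10:
            raise ValueError("need >= 10 post-bleach samples")


@dataclass
class NormalizedFRAP:
    time: np.ndarray
    intensity: np.ndarray
    bleach_index: int


def normalize_frap(trace: FRAPTrace) -> NormalizedFRAP:
    """Normalize so the mean pre-bleach intensity equals 1.

    With a reference region, I/I_ref is formed first (double normalization),
    cancelling acquisition bleaching shared by both regions.
    """
    y = trace.roi_intensity
    if trace.reference_intensity is not None:
        y = y / trace.reference_intensity
    pre = y[:trace.bleach_index]
    return NormalizedFRAP(time=trace.time.copy(),
                          intensity=y / np.mean(pre),
                          bleach_index=trace.bleach_index)


@dataclass
class FRAPFit:
    f_mobile: float
    tau: float
    i0: float
    plateau: float
    residual_rms: float
    flagged: bool = False
    message: str = ""


def fit_recovery(norm: NormalizedFRAP, fit_i0: bool = False) -> FRAPFit:
    """Fit the post-bleach recovery and return (f_mobile, tau, I0).

    ``I0`` is the first post-bleach sample by default (``fit_i0=True`` frees
    it as a parameter).  f_mobile is clipped to [0, 1.05]; values above 1
    are flagged as over-recovery.  Requires a bleach depth 1 - I0 >= 0.05.
    """
    b = norm.bleach_index
    t = norm.time[b:] - norm.time[b]
    y = norm.intensity[b:]
    i0 = float(y[0])
    if 1.0 - i0 < 0.05:
        raise ValueError(f"bleach too shallow (depth {1 - i0:.3f} < 0.05)")

    if np.ptp(y) < 1e-12:
        # no measurable recovery: plateau equals the bleached level
        return FRAPFit(f_mobile=0.0, tau=np.nan, i0=i0, plateau=i0,
                       residual_rms=0.0, message="flat post-bleach trace")

    tau0 = max(t[-1] / 5.0, t[1] - t[0])
    try:
        if fit_i0:
            model = lambda tt, p, tau, ii: ii + (p - ii) * (1 - np.exp(-tt / tau))
            popt, _ = curve_fit(model, t, y, p0=(float(y[-1]), tau0, i0), maxfev=10000)
            plateau, tau, i0 = (float(v) for v in popt)
        else:
            model = lambda tt, p, tau: i0 + (p - i0) * (1 - np.exp(-tt / tau))
            popt, _ = curve_fit(model, t, y, p0=(float(y[-1]), tau0), maxfev=10000)
            plateau, tau = float(popt[0]), float(popt[1])
    except RuntimeError as exc:
        return FRAPFit(f_mobile=np.nan, tau=np.nan, i0=i0, plateau=np.nan,
                       residual_rms=np.nan, flagged=True,
                       message=f"recovery fit did not converge: {exc}")

    resid = y - model(t, *popt)
    f_mobile = (plateau - i0) / (1.0 - i0)
    flagged, message = False, ""
    if f_mobile > 1.0:
        flagged, message = True, f"over-recovery (f_mobile = {f_mobile:.3f} > 1)"
    f_mobile = float(np.clip(f_mobile, 0.0, 1.05))
    return FRAPFit(f_mobile=f_mobile, tau=tau, i0=i0, plateau=plateau,
                   residual_rms=float(np.sqrt(np.mean(resid ** 2))),
                   flagged=flagged, message=message)
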