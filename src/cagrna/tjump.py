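"""Kinetic (amplitude-based) melting analysis of consecutive T-jump FRET traces.

In-cell melting curves cannot be measured with fully resolved folded and
unfolded baselines: the accessible temperature window is narrow and only a
few points beyond T_m can be recorded.  The kinetic route used here instead
steps the sample through a ladder of fast temperature jumps (typically 19
jumps of 25 s each, under 8 min total) and, for every jump, fits the slow
relaxation of the FRET donor/acceptor ratio to a single exponential.  The
relaxation *amplitude* of jump k reports the change in unfolded population
between the two neighbouring equilibria, so the amplitude-versus-temperature
curve is fit by the finite-difference two-state model

    a_k = c * [f_u(T_k) - f_u(T_{k-1})] + m * (T_k - T_{k-1})

with f_u from :mod:`cagrna.thermo` under dG_u(T) = g1*(T - T_m).  The free
parameters are (T_m, g1) plus a signal scale c and a linear drift m that
absorbs dye/baseline trends.  Sample temperature per jump is calibrated from
the temperature-dependent fluorescence of a Rhodamine B reference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares

from . import thermo
from .thermo import MeltingParameters

logger = logging.getLogger(__name__)

__all__ = [
    "JumpProtocol",
    "TemperatureCalibration",
    "RelaxationTrace",
    "RelaxationFit",
    "AmplitudeCurve",
    "MeltingFitResult",
    "calibrate_temperature",
    "fit_relaxation",
    "build_amplitude_curve",
    "fit_melting",
]


@dataclass(frozen=True)
class JumpProtocol:
    """Ladder of consecutive temperature jumps.

    ``target_temperatures`` are the post-jump equilibrium temperatures (K),
    strictly increasing; ``start_temperature`` is the pre-ladder temperature
    T_0.  Each jump dwells ``dwell_per_jump`` seconds (default 25 s).
    """

    target_temperatures: tuple
    start_temperature: float
    dwell_per_jump: float = 25.0

    def __post_init__(self):
        temps = np.asarray(self.target_temperatures, dtype=float)
        object.__setattr__(self, "target_temperatures", tuple(temps))
        if temps.size < 1:
            raise ValueError("protocol needs at least one jump")
        if np.any(np.diff(temps) <= 0):
            raise ValueError("target temperatures must be strictly increasing")
        if self.dwell_per_jump <= 0:
            raise ValueError("dwell_per_jump must be positive")

    @property
    def n_jumps(self) -> int:
        return len(self.target_temperatures)

    @property
    def total_duration(self) -> float:
        """Total ladder duration, s (= n_jumps * dwell)."""
        return self.n_jumps * self.dwell_per_jump


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class TemperatureCalibration:
    """Exponential Rhodamine-B fluorescence thermometer F(T) = F_ref*exp(-s*(T-T_ref)).

    Rhodamine B fluorescence decreases monotonically with temperature; the
    decrease is well described by a single exponential over the ladder range.
    ``sensitivity`` s is in 1/K (positive).  ``fit_range`` records the
    temperature span of the reference data used to fit the model, for
    extrapolation warnings.
    """

    f_ref: float
    t_ref: float
    sensitivity: float
    fit_range: tuple = (0.0, np.inf)

    def __post_init__(self):
        if self.f_ref <= 0 or self.sensitivity <= 0:
            raise CalibrationError("f_ref and sensitivity must be positive")

    @classmethod
    def from_pairs(cls, fluorescence, temperature) -> "TemperatureCalibration":
        """Least-squares fit of (F_ref, s) to reference (F, T) pairs.

        Linear regression on log F; requires >= 2 pairs with fluorescence
        strictly decreasing in temperature.
        """
        f = np.asarray(fluorescence, dtype=float)
        t = np.asarray(temperature, dtype=float)
        if f.size < 2 or f.size != t.size:
            raise CalibrationError("need at least 2 matched reference pairs")
        order = np.argsort(t)
        f, t = f[order], t[order]
        if np.any(np.diff(f) >= 0):
            raise CalibrationError("reference fluorescence must decrease with temperature")
        slope, intercept = np.polyfit(t, np.log(f), 1)
        t_ref = float(t[0])
        f_ref = float(np.exp(intercept + slope * t_ref))
        return cls(f_ref=f_ref, t_ref=t_ref, sensitivity=float(-slope),
                   fit_range=(float(t[0]), float(t[-1])))

    def to_temperature(self, fluorescence):
        """Invert the thermometer: T = T_ref + ln(F_ref/F)/s, K."""
        f = np.asarray(fluorescence, dtype=float)
        if np.any(f <= 0):
            raise CalibrationError("fluorescence must be positive")
        T = self.t_ref + np.log(self.f_ref / f) / self.sensitivity
        lo, hi = self.fit_range
        span = (hi - lo) if np.isfinite(hi) else 0.0
        if span and (np.any(T < lo - 0.1 * span) or np.any(T > hi + 0.1 * span)):
            warnings.warn("fluorescence outside calibrated range; extrapolating",
                          stacklevel=2)
        return float(T) if T.ndim == 0 else T


def calibrate_temperature(ref_fluorescence, calib: TemperatureCalibration):
    """Map a reference-dye fluorescence series to sample temperature (K)."""
    return calib.to_temperature(ref_fluorescence)


@dataclass
class RelaxationTrace:
    """One temperature jump: donor/acceptor fluorescence versus time.

    ``time`` is monotone (s); jump onset is at ``time == onset_time``
    (default: the first sample).  ``temperature`` optionally carries the
    calibrated sample-temperature series used for onset detection.
    """

    time: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    pre_jump_T: float
    post_jump_T: float
    temperature: np.ndarray | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if not (self.time.shape == self.donor.shape == self.acceptor.shape):
            raise ValueError("time, donor, acceptor must have matching shapes")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.donor <= 0) or np.any(self.acceptor <= 0):
            raise ValueError("fluorescence channels must be positive")

    @property
    def ratio(self) -> np.ndarray:
        """Donor/acceptor ratio; increases when the hairpin unfolds."""
        return self.donor / self.acceptor

    def onset_index(self) -> int:
        """First sample after the jump onset.

        If a calibrated temperature series is attached, the onset is the
        first sample whose temperature exceeds the midpoint between the pre-
        and post-jump targets; otherwise the trace is assumed to start at
        the jump (index 0).
        """
        if self.temperature is None:
            return 0
        mid = 0.5 * (self.pre_jump_T + self.post_jump_T)
        above = np.nonzero(np.asarray(self.temperature) > mid)[0]
        if above.size == 0:
            raise ValueError("no sample beyond the jump midpoint; onset not identifiable")
        return int(above[0])


@dataclass
class RelaxationFit:
    """Single-exponential fit of one post-jump relaxation.

    ``amplitude`` is signed: its sign carries the direction of the
    equilibrium shift (positive = D/A increase = net unfolding).
    """

    amplitude: float
    k_obs: float
    offset: float
    residual_rms: float
    sigma_amplitude: float = np.nan
    post_jump_T: float = np.nan
    flagged: bool = False
    message: str = ""


def _relax_model(t, offset, a, k):
    return offset + a * (1.0 - np.exp(np.clip(-k * t, -700.0, 700.0)))


def fit_relaxation(trace: RelaxationTrace, signal: str = "ratio") -> RelaxationFit:
    """Fit D/A(t) = offset + a*(1 - exp(-k_obs*(t - t0))) after the jump.

    ``signal`` selects the observable: ``"ratio"`` (default, donor/acceptor)
    or ``"donor"``.  Flat traces are returned flagged with amplitude 0;
    non-converged fits are flagged and excluded downstream.
    """
    i0 = trace.onset_index()
    t = trace.time[i0:] - trace.time[i0]
    y = (trace.ratio if signal == "ratio" else trace.donor)[i0:]
    if t.size < 10:
        raise ValueError(f"need >= 10 post-jump samples, got {t.size}")

    spread = np.ptp(y)
    if spread < 1e-12 * max(1.0, abs(float(np.mean(y)))):
        return RelaxationFit(amplitude=0.0, k_obs=np.nan, offset=float(y[0]),
                             residual_rms=float(np.std(y)), post_jump_T=trace.post_jump_T,
                             flagged=True, message="flat trace; rate unidentifiable")

    a0 = float(y[-1] - y[0])
    # crude rate guess: time to cover 63% of the span
    target = y[0] + 0.632 * a0
    crossed = np.nonzero((y - target) * np.sign(a0 or 1.0) >= 0)[0]
    t63 = t[crossed[0]] if crossed.size and t[crossed[0]] > 0 else t[-1] / 3.0
    p0 = (float(y[0]), a0, 1.0 / t63)
    try:
        popt, pcov = curve_fit(_relax_model, t, y, p0=p0, maxfev=10000,
                               xtol=1e-12, ftol=1e-12)
    except RuntimeError as exc:
        return RelaxationFit(amplitude=np.nan, k_obs=np.nan, offset=np.nan,
                             residual_rms=np.nan, post_jump_T=trace.post_jump_T,
                             flagged=True, message=f"fit did not converge: {exc}")
    offset, a, k = (float(v) for v in popt)
    if k <= 0:
        return RelaxationFit(amplitude=np.nan, k_obs=k, offset=offset, residual_rms=np.nan,
                             post_jump_T=trace.post_jump_T, flagged=True,
                             message="non-positive relaxation rate")
    resid = y - _relax_model(t, *popt)
    sigma_a = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.nan
    return RelaxationFit(amplitude=a, k_obs=k, offset=offset,
                         residual_rms=float(np.sqrt(np.mean(resid ** 2))),
                         sigma_amplitude=sigma_a, post_jump_T=trace.post_jump_T)


@dataclass
class AmplitudeCurve:
    """Slow-phase amplitude of each jump versus its final temperature."""

    temperatures: np.ndarray      # post-jump temperatures T_k, strictly increasing
    amplitudes: np.ndarray
    sigmas: np.ndarray
    start_temperature: float      # T_0 before the first jump

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if not (len(self.temperatures) == len(self.amplitudes) == len(self.sigmas)):
            raise ValueError("mismatched curve lengths")

    def __len__(self) -> int:
        return len(self.temperatures)


def build_amplitude_curve(fits, protocol: JumpProtocol,
                          temperatures=None) -> AmplitudeCurve:
    """Pair per-jump amplitudes with calibrated post-jump temperatures.

    ``fits`` must have one entry per executed jump, in ladder order.
    Flagged fits are excluded with a log record; if every fit is flagged the
    melting analysis cannot proceed and a ``ValueError`` is raised.
    ``temperatures`` overrides the protocol targets with calibrated values.
    """
    fits = list(fits)
    if len(fits) != protocol.n_jumps:
        raise ValueError(f"expected {protocol.n_jumps} fits, got {len(fits)}")
    temps = np.asarray(temperatures if temperatures is not None
                       else protocol.target_temperatures, dtype=float)
    keep, amps, sigs, ts = [], [], [], []
    for k, fit in enumerate(fits):
        if fit.flagged and fit.message != "flat trace; rate unidentifiable":
            logger.info("jump %d at %.1f K excluded: %s", k, temps[k], fit.message)
            continue
        ts.append(temps[k])
        amps.append(fit.amplitude)
        sigs.append(fit.sigma_amplitude)
        keep.append(k)
    if not keep:
        raise ValueError("all relaxation fits flagged; no amplitude curve")
    return AmplitudeCurve(np.array(ts), np.array(amps), np.array(sigs),
                          start_temperature=protocol.start_temperature)


@dataclass
class MeltingFitResult:
    """Full result of the amplitude-curve melting fit."""

    params: MeltingParameters
    scale: float                 # c, signal units per unit population change
    drift: float                 # m, signal units per K
    sse: float
    n_points: int
    covariance: np.ndarray       # 4x4 over (tm, g1, c, m)
    flagged: bool = False
    message: str = ""

    @property
    def dg37(self) -> float:
        return thermo.delta_g_37(self.params)


def _amplitude_model(theta, t_prev, t_post):
    tm, g1, c, m = theta
    fu_post = thermo.unfolded_fraction(g1 * (t_post - tm), t_post)
    fu_prev = thermo.unfolded_fraction(g1 * (t_prev - tm), t_prev)
    return c * (np.asarray(fu_post) - np.asarray(fu_prev)) + m * (t_post - t_prev)


def fit_melting(curve: AmplitudeCurve, start_T: float | None = None,
                weighted: bool = False) -> MeltingFitResult:
    """Fit (T_m, g1, c, m) to an amplitude-versus-temperature curve.

    Nonlinear least squares of a_k = c*[f_u(T_k) - f_u(T_{k-1})] + m*dT_k
    with multi-start initialization: T_m started at the temperature of the
    largest |amplitude| and at the ladder midpoint, g1 at {-0.2, -0.5, -1.0}
    kJ/mol/K; the start with the lowest SSE wins, ties broken by smaller
    |g1|.  Parameter uncertainties come from the local covariance of the
    winning fit (residual-variance scaled), feeding Gaussian error
    propagation of dG37 downstream.
    """
    t_post = curve.temperatures
    n = len(curve)
    if n < 6:
        raise ValueError(f"need >= 6 amplitude points, got {n}")
    t0 = curve.start_temperature if start_T is None else start_T
    t_prev = np.concatenate(([t0], t_post[:-1]))
    if t_post[-1] - t0 < 20.0:
        raise ValueError("amplitude curve must span >= 20 K")
    a = curve.amplitudes
    w = None
    if weighted and np.all(np.isfinite(curve.sigmas)) and np.all(curve.sigmas > 0):
        w = 1.0 / curve.sigmas

    scale0 = float(np.sum(a))
    if abs(scale0) < 1e-3 * np.max(np.abs(a) if n else 1.0):
        scale0 = float(np.max(np.abs(a)) * n / 4.0) or 1.0

    def resid(theta):
        r = _amplitude_model(theta, t_prev, t_post) - a
        return r * w if w is not None else r

    tm_starts = (float(t_post[np.argmax(np.abs(a))]),
                 float(0.5 * (t_post[0] + t_post[-1])))
    best = None
    for tm0 in tm_starts:
        for g10 in (-0.2, -0.5, -1.0):
            try:
                sol = least_squares(resid, x0=(tm0, g10, scale0, 0.0),
                                    xtol=1e-12, ftol=1e-12, gtol=1e-12,
                                    max_nfev=500 * 4)
            except Exception:  # pragma: no cover - defensive
                continue
            sse = float(2 * sol.cost)
            if (best is None or sse < best[0] - 1e-10 * max(best[0], 1e-300)
                    or (abs(sse - best[0]) <= 1e-10 * max(best[0], 1e-300)
                        and abs(sol.x[1]) < abs(best[1].x[1]))):
                best = (sse, sol)
    if best is None:
        raise RuntimeError("melting fit failed to converge from any start")
    sse, sol = best
    tm, g1, c, m = (float(v) for v in sol.x)

    dof = max(n - 4, 1)
    jac = sol.jac
    try:
        cov = np.linalg.inv(jac.T @ jac) * (sse / dof)
    except np.linalg.LinAlgError:
        cov = np.full((4, 4), np.nan)

    flagged, message = False, ""
    amax = float(np.max(np.abs(a))) or 1.0
    if abs(c) < 1e-6 * amax:
        flagged, message = True, "no folding signal (c ~ 0); T_m unidentifiable"
    elif g1 >= 0:
        flagged, message = True, "non-melting signal (g1 >= 0)"
        warnings.warn("fitted g1 >= 0: amplitude curve has no melting signature",
                      stacklevel=2)

    if tm <= 0:
        flagged, message = True, f"unphysical fitted T_m = {tm:.3g} K"
        tm = np.finfo(float).tiny
    params = MeltingParameters(
        tm=tm, g1=g1,
        sigma_tm=float(np.sqrt(max(cov[0, 0], 0.0))),
        sigma_g1=float(np.sqrt(max(cov[1, 1], 0.0))),
        cov_tm_g1=float(cov[0, 1]),
    )
    return MeltingFitResult(params=params, scale=c, drift=m, sse=sse,
                            n_points=n, covariance=cov,
                            flagged=flagged, message=message)
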