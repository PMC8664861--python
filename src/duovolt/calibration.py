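"""Indicator characterisation: sigmoid F-V fits, exponential kinetics fits,
detection-limit algebra, and goodness of fit."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FitError",
    "FVFit",
    "KineticsFit",
    "DetectionLimit",
    "fit_fv_curve",
    "fit_double_exponential",
    "fit_single_exponential",
    "detection_limit",
    "goodness_of_fit",
]


class FitError(RuntimeError):
    """Raised when a curve fit cannot be performed or does not converge."""


@dataclass(frozen=True)
class FVFit:
    """Fitted Boltzmann fluorescence-voltage relationship.

    ``f(V) = baseline + amplitude / (1 + exp(-(V - v_half)/k_slope))`` with
    ``k_slope > 0``; a negative-going sensor has negative ``amplitude``.
    """

    v_half: float
    k_slope: float
    amplitude: float
    baseline: float
    rss: float

    def predict(self, v) -> np.ndarray:
        v = np.asarray(v, dtype=np.float64)
        return self.baseline + self.amplitude / (1.0 + np.exp(-(v - self.v_half) / self.k_slope))

    def slope_at(self, v: float) -> float:
        """Analytic derivative of the fitted sigmoid at ``v``, in
        %dF/F per mV (input data are fractions)."""
        e = math.exp(-(v - self.v_half) / self.k_slope)
        return 100.0 * self.amplitude * e / (self.k_slope * (1.0 + e) ** 2)


@dataclass(frozen=True)
class KineticsFit:
    """Double-exponential fit; ``tau1 <= tau2`` (tau1 is the fast component)."""

    a1: float
    a2: float
    tau1: float
    tau2: float
    rss: float
    mode: str = "rise"


@dataclass(frozen=True)
class DetectionLimit:
    """Smallest resolvable voltage change: |(mean - 3*SD)/slope|."""

    limit: float
    baseline_mean: float
    baseline_sd: float
    slope: float


def _boltzmann(v, v_half, k_slope, amplitude, baseline):
    return baseline + amplitude / (1.0 + np.exp(-(v - v_half) / k_slope))


def fit_fv_curve(voltages, dff) -> FVFit:
    """Least-squares Boltzmann fit of steady-state dF/F versus voltage.

    Requires at least 5 distinct voltages spanning the sigmoid; flat data
    raise :class:`FitError`.
    """
    v = np.asarray(voltages, dtype=np.float64)
    f = np.asarray(dff, dtype=np.float64)
    if v.shape != f.shape or np.unique(v).size < 5:
        raise FitError("need >= 5 distinct voltages")
    if np.ptp(f) < 1e-12:
        raise FitError("constant dF/F data cannot constrain a sigmoid")
    span = np.ptp(v)
    amp0 = f[np.argmax(v)] - f[np.argmin(v)]
    p0 = (float(np.median(v)), span / 6.0, amp0 if amp0 != 0 else np.ptp(f), float(f.min()))
    bounds = ([v.min() - 2 * span, 1e-6, -np.inf, -np.inf],
              [v.max() + 2 * span, 10 * span, np.inf, np.inf])
    try:
        popt, _ = curve_fit(_boltzmann, v, f, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"Boltzmann fit failed: {exc}") from exc
    rss = float(np.sum((f - _boltzmann(v, *popt)) ** 2))
    return FVFit(v_half=popt[0], k_slope=popt[1], amplitude=popt[2], baseline=popt[3], rss=rss)


def _double_exp_rise(t, a1, a2, tau1, tau2):
    return a1 * (1.0 - np.exp(-t / tau1)) + a2 * (1.0 - np.exp(-t / tau2))


def fit_double_exponential(t, y) -> KineticsFit:
    """Fit a step response with a sum of two saturating exponentials.

    Rising responses are fitted as ``a1 (1 - e^(-t/tau1)) + a2 (1 - e^(-t/tau2))``;
    decaying responses are mirrored (the same form is fitted to the negated,
    baseline-subtracted data and the amplitudes carry the sign).  ``tau1``
    is reported as the fast component.
    """
    t = np.asarray(t, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if t.size != y.size or t.size < 20:
        raise FitError("need >= 20 samples")
    t0 = t - t[0]
    resp = y - y[0]
    plateau = np.mean(resp[-max(3, resp.size // 10):])
    if abs(plateau) < 1e-12:
        raise FitError("response has no plateau amplitude")
    sign = 1.0 if plateau > 0 else -1.0
    r = sign * resp
    plat = sign * plateau
    # heuristics: time to 30% / 90% of plateau bracket the two time constants
    t30 = t0[np.argmax(r >= 0.3 * plat)]
    t90 = t0[np.argmax(r >= 0.9 * plat)]
    tau1_0 = max(t30 / 0.35, 1e-4)
    tau2_0 = max(t90 / 2.3, 2 * tau1_0)
    p0 = (0.7 * plat, 0.3 * plat, tau1_0, tau2_0)
    bounds = ([0.0, 0.0, 1e-6, 1e-6], [10 * plat, 10 * plat, 1e4, 1e4])
    try:
        popt, _ = curve_fit(_double_exp_rise, t0, r, p0=p0, bounds=bounds, maxfev=40000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"double-exponential fit did not converge: {exc}") from exc
    a1, a2, tau1, tau2 = popt
    if tau1 > tau2:  # relabel so tau1 is fast
        a1, a2, tau1, tau2 = a2, a1, tau2, tau1
    rss = float(np.sum((r - _double_exp_rise(t0, *popt)) ** 2))
    return KineticsFit(a1=sign * a1, a2=sign * a2, tau1=tau1, tau2=tau2, rss=rss,
                       mode="rise" if sign > 0 else "decay")


def fit_single_exponential(t, y) -> tuple[float, float]:
    """Least-squares fit of ``y = c * exp(-t/tau)`` for decaying data.

    Used for photobleaching curves (normalise so y(0) = 1 first) and spike
    decay.  Returns ``(tau, c)``; increasing or constant data raise
    :class:`FitError`.
    """
    t = np.asarray(t, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if t.size != y.size or t.size < 10:
        raise FitError("need >= 10 samples")
    head = np.mean(y[: max(2, y.size // 10)])
    tail = np.mean(y[-max(2, y.size // 10):])
    if tail >= head:
        raise FitError("data are not decaying")
    pos = y > 0
    if pos.sum() >= 2:  # log-linear initial guess
        slope, inter = np.polyfit(t[pos], np.log(y[pos]), 1)
        tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0])
        c0 = math.exp(inter)
    else:
        tau0, c0 = t[-1] - t[0], head
    try:
        popt, _ = curve_fit(lambda tt, c, tau: c * np.exp(-tt / tau), t, y,
                            p0=(c0, max(tau0, 1e-6)),
                            bounds=([0, 1e-9], [np.inf, np.inf]), maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"single-exponential fit failed: {exc}") from exc
    return float(popt[1]), float(popt[0])


def detection_limit(baseline_dff_percent, slope_percent_per_mv: float) -> DetectionLimit:
    """Detection limit (mean - 3*SD)/slope, reported as a positive mV value.

    ``baseline_dff_percent`` are dF/F samples (in %) measured while the true
    voltage change is below 1 mV; ``slope_percent_per_mv`` is the local F-V
    sensitivity (negative for a negative-going sensor, so the signs cancel).
    """
    x = np.asarray(baseline_dff_percent, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need >= 2 baseline samples")
    if slope_percent_per_mv == 0:
        raise ZeroDivisionError("slope must be nonzero")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    limit = abs((mean - 3.0 * sd) / slope_percent_per_mv)
    return DetectionLimit(limit=limit, baseline_mean=mean, baseline_sd=sd,
                          slope=slope_percent_per_mv)


def goodness_of_fit(observed, predicted) -> float:
    """Conventional coefficient of determination, 1 - SS_res/SS_tot."""
    o = np.asarray(observed, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    if o.shape != p.shape or o.size < 2:
        raise ValueError("observed and predicted must have equal length >= 2")
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed data are constant; R^2 undefined")
    ss_res = float(np.sum((o - p) ** 2))
    return 1.0 - ss_res / ss_tot
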