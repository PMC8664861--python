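"""Population- and field-level analyses: LFP filtering, correlation structure,
seizure onset delays, recruitment order, and propagation-pattern labels."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .events import robust_sd
from .traces import Trace, TraceSet

__all__ = [
    "CorrMatrix",
    "SeizureMarkers",
    "bandpass_lfp",
    "downsample_trace",
    "correlation_matrix",
    "correlation_vs_distance",
    "windowed_lfp_optical_correlation",
    "seizure_onsets",
    "recruitment_order",
    "classify_propagation_pattern",
]


@dataclass
class CorrMatrix:
    labels: list[str]
    r: np.ndarray  # zero-lag Pearson; NaN flags constant traces
    n_samples: int

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.float64)
        valid = np.isfinite(self.r)
        if np.any(np.abs(self.r[valid]) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class SeizureMarkers:
    lfp_onset: float | None
    signal_onsets: dict  # label -> onset (s) or None
    delays: dict = field(init=False)  # label -> onset - lfp_onset
    recruitment_times: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.delays = {}
        for k, v in self.signal_onsets.items():
            self.delays[k] = (v - self.lfp_onset
                              if v is not None and self.lfp_onset is not None else None)


def bandpass_lfp(lfp: Trace, low: float = 0.2, high: float = 50.0, order: int = 4) -> Trace:
    """Zero-phase Butterworth band-pass of the LFP; DC removed."""
    if not 0 < low < high:
        raise ValueError("band edges must satisfy 0 < low < high")
    fs = lfp.rate
    if high >= fs / 2:
        raise ValueError("upper band edge must be below the Nyquist frequency")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, lfp.y - lfp.y.mean())
    return Trace(lfp.t, y, kind="electrical", label=lfp.label)


def downsample_trace(tr: Trace, target_rate: float) -> Trace:
    """Windowed (box) averaging to a lower rate; sample k averages the span
    [k/target_rate, (k+1)/target_rate)."""
    fs = tr.rate
    if target_rate > fs:
        raise ValueError("target rate exceeds source rate")
    n_out = int(math.floor(tr.y.size / fs * target_rate))
    edges = np.floor(np.arange(n_out + 1) * fs / target_rate).astype(int)
    sums = np.add.reduceat(tr.y, edges[:-1])
    y = sums / np.diff(edges)
    t = tr.t[0] + np.arange(n_out) / target_rate
    return Trace(t, y, kind=tr.kind, label=tr.label)


def correlation_matrix(traces: TraceSet) -> CorrMatrix:
    """Zero-lag Pearson correlation for all trace pairs.

    A constant trace yields NaN in its row/column (flagged, not an error);
    the diagonal is exactly 1 and the matrix exactly symmetric.
    """
    mat = traces.as_matrix()
    sd = mat.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(mat)
    r = np.clip(r, -1.0, 1.0)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0
    return CorrMatrix(labels=traces.labels, r=r, n_samples=mat.shape[1])


def correlation_vs_distance(m: CorrMatrix, centroids: dict) -> dict:
    """All n(n-1)/2 (distance, r) pairs plus a linear trend summary.

    ``centroids`` maps label -> (x, y) in micrometres.
    """
    missing = [lab for lab in m.labels if lab not in centroids]
    if missing:
        raise KeyError(f"missing centroid for {missing[0]!r}")
    pos = np.array([centroids[lab] for lab in m.labels], dtype=np.float64)
    n = len(m.labels)
    dists, rs = [], []
    for i in range(n):
        for j in range(i + 1, n):
            rij = m.r[i, j]
            if not np.isfinite(rij):
                continue
            dists.append(float(np.hypot(*(pos[i] - pos[j]))))
            rs.append(float(rij))
    dists = np.asarray(dists)
    rs = np.asarray(rs)
    out = dict(distance=dists, r=rs, mean_r=float(rs.mean()) if rs.size else None,
               slope=None, intercept=None, slope_stderr=None)
    if rs.size >= 3 and np.ptp(dists) > 0:
        res = stats.linregress(dists, rs)
        out.update(slope=float(res.slope), intercept=float(res.intercept),
                   slope_stderr=float(res.stderr))
    return out


def _norm_xcorr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Full normalised cross-correlation of two z-scored signals."""
    a = (a - a.mean())
    b = (b - b.mean())
    denom = math.sqrt(float(np.sum(a**2)) * float(np.sum(b**2)))
    if denom == 0:
        raise ValueError("constant segment; cross-correlation undefined")
    return np.correlate(a, b, mode="full") / denom


def windowed_lfp_optical_correlation(
    lfp: Trace,
    ofp: Trace,
    onset: float,
    windows: tuple[tuple[float, float], ...] = ((0.0, 10.0), (10.0, 20.0)),
    max_lag: float = 0.25,
) -> list[dict]:
    """Peak |cross-correlation| between LFP and optical field potential in
    look-back windows before seizure onset.

    The LFP is first box-averaged down to the optical rate.  For each
    (lo, hi) window the segment [onset - hi, onset - lo] of both signals is
    cross-correlated (normalised); the peak magnitude within ``max_lag`` and
    its lag are reported.
    """
    rate = ofp.rate
    lfp30 = downsample_trace(lfp, rate) if lfp.rate > rate * (1 + 1e-9) else lfp
    out = []
    for lo, hi in windows:
        t_lo, t_hi = onset - hi, onset - lo
        if t_lo < ofp.t[0] - 1e-9 or t_lo < lfp30.t[0] - 1e-9:
            raise ValueError(f"window ({lo}, {hi}) s before onset escapes the recording")
        sel_o = (ofp.t >= t_lo) & (ofp.t < t_hi)
        sel_l = (lfp30.t >= t_lo) & (lfp30.t < t_hi)
        a = lfp30.y[sel_l]
        b = ofp.y[sel_o]
        n = min(a.size, b.size)
        # remove the within-window linear trend so slow drift (bleach residue,
        # approaching-seizure baseline shift) does not mask event coupling
        k = np.arange(n)
        a = a[:n] - np.polyval(np.polyfit(k, a[:n], 1), k)
        b = b[:n] - np.polyval(np.polyfit(k, b[:n], 1), k)
        xc = _norm_xcorr(a, b)
        lags = (np.arange(xc.size) - (n - 1)) / rate
        sel = np.abs(lags) <= max_lag
        k = np.argmax(np.abs(xc[sel]))
        out.append(dict(window=(lo, hi), peak=float(np.abs(xc[sel])[k]),
                        lag=float(lags[sel][k])))
    return out


def _sustained_onset(
    t: np.ndarray, folded: np.ndarray, thr: float, sustain: float, rate: float
) -> float | None:
    """First time ``folded`` exceeds ``thr`` continuously for ``sustain`` s."""
    above = folded > thr
    need = max(1, int(round(sustain * rate)))
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= need:
            return float(t[i - need + 1])
    return None


def seizure_onsets(
    lfp: Trace,
    tracesets: dict,
    sustain: float | dict = 0.5,
    baseline_window: tuple[float, float] | None = None,
    threshold_sd: float = 3.0,
    polarity: dict | None = None,
    min_fraction: float = 0.0,
) -> SeizureMarkers:
    """Locate seizure onset in the LFP and in each optical trace.

    LFP onset: first time the rectified band-passed LFP exceeds
    ``threshold_sd`` times its baseline SD, sustained for ``sustain`` seconds.
    Per-signal onsets apply the same rule to each dF/F trace in the channel's
    depolarising direction (``polarity`` maps channel -> -1/+1, default
    voltage -1, calcium +1).  Calcium onsets double as recruitment times.
    """
    polarity = polarity or {"voltage": -1, "calcium": +1}
    if baseline_window is None:
        baseline_window = (lfp.t[0], lfp.t[0] + 0.25 * lfp.duration)

    def _sustain_for(channel: str) -> float:
        if isinstance(sustain, dict):
            return sustain.get(channel, 0.5)
        return sustain

    def _onset(tr: Trace, direction: int | None, sus: float) -> float | None:
        sel = (tr.t >= baseline_window[0]) & (tr.t < baseline_window[1])
        base = tr.y[sel]
        ref = np.median(base)
        # moving average: oscillatory ictal activity stays above threshold
        # through zero crossings and noise dips do not break the sustained
        # run; the rectified LFP keeps a short window so interictal spike
        # clusters do not blur into a false sustained elevation
        if direction is None:
            w = max(1, int(round(0.25 * tr.rate)))
            x = np.abs(tr.y - ref)
        else:
            w = max(1, int(round(min(0.5, max(0.25, sus / 4.0)) * tr.rate)))
            x = (tr.y - ref) * direction
        # causal (trailing) window: the smoothed signal never rises before the
        # raw signal does, so onsets are not biased early
        folded = np.convolve(x, np.ones(w) / w, mode="full")[: x.size]
        fbase = folded[sel]
        ref_f = np.median(fbase)
        sd = robust_sd(fbase)
        if sd == 0:
            sd = fbase.std() or 1e-12
        # the optional relative floor keeps small cross-talk (e.g. neuropil
        # contamination well below the signal's own ictal amplitude) from
        # triggering a premature onset
        thr = ref_f + max(threshold_sd * sd,
                          min_fraction * (float(folded.max()) - ref_f))
        return _sustained_onset(tr.t, folded, thr, sus, tr.rate)

    lfp_onset = _onset(lfp, None, _sustain_for("lfp"))
    onsets: dict[str, float | None] = {}
    recruit: dict[str, float] = {}
    for channel, ts in tracesets.items():
        d = polarity.get(channel, +1)
        for tr in ts:
            key = f"{channel}:{tr.label}"
            onsets[key] = _onset(tr, d, _sustain_for(channel))
            if channel == "calcium" and onsets[key] is not None:
                recruit[tr.label] = onsets[key]
    return SeizureMarkers(lfp_onset=lfp_onset, signal_onsets=onsets,
                          recruitment_times=recruit)


def recruitment_order(onsets: dict, positions: dict) -> dict:
    """Order recruited cells and estimate wavefront speed.

    Fits onset = a + g . (x, y) by least squares; the gradient direction is the
    propagation axis and speed = 1/|g| (um/s).  Synchronous onsets (|g| ~ 0)
    flag the speed as infinite.
    """
    labels = [k for k, v in onsets.items() if v is not None]
    if len(labels) < 3:
        raise ValueError("need >= 3 recruited cells")
    t = np.array([onsets[k] for k in labels], dtype=np.float64)
    pos = np.array([positions[k] for k in labels], dtype=np.float64)
    order = [labels[i] for i in np.argsort(t)]
    A = np.column_stack([np.ones_like(t), pos])
    coef, *_ = np.linalg.lstsq(A, t, rcond=None)
    grad = coef[1:]
    gnorm = float(np.hypot(*grad))
    sync = bool(gnorm < 1e-9 or np.ptp(t) < 1e-9)
    speed = math.inf if sync else 1.0 / gnorm
    proj = pos @ (grad / gnorm) if not sync else np.zeros_like(t)
    pred = A @ coef
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    r2 = 1.0 - float(np.sum((t - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return dict(order=order, delays={k: float(v - t.min()) for k, v in zip(labels, t)},
                speed=speed, synchronous=sync,
                axis=(grad / gnorm).tolist() if not sync else None,
                projected_distance=dict(zip(labels, proj.tolist())), r_squared=r2)


def classify_propagation_pattern(
    area_traces: TraceSet,
    window: tuple[float, float],
    centroids: dict,
    sync_tol: float = 0.033,
    coverage_frac: float = 0.8,
    threshold_sd: float = 3.0,
    polarity: int = -1,
    corr_min: float = 0.7,
) -> dict:
    """Label one population event as synchronous / propagating / partial.

    An area is active when its trace crosses ``threshold_sd`` baseline SDs
    (channel polarity) inside ``window``.  Active fraction < ``coverage_frac``
    gives ``partial``; otherwise an onset spread <= ``sync_tol`` gives
    ``synchronous``; otherwise a monotonic onset-position relationship (|r| >=
    ``corr_min`` along the onset-gradient axis) gives ``propagating``, and
    anything else falls back to ``synchronous`` with ``low_confidence`` set.
    """
    if len(area_traces) < 4:
        raise ValueError("need a grid of >= 4 areas")
    lo, hi = window
    onsets: dict[str, float] = {}
    for tr in area_traces:
        folded = (tr.y - np.median(tr.y)) * polarity
        sd = robust_sd(tr.y)
        if sd == 0:
            continue
        sel = (tr.t >= lo) & (tr.t < hi)
        above = folded > threshold_sd * sd
        hit = np.flatnonzero(above & sel)
        if hit.size:
            onsets[tr.label] = float(tr.t[hit[0]])
    if not onsets:
        raise ValueError("no active areas in the event window")
    frac = len(onsets) / len(area_traces)
    result = dict(active_fraction=frac, onsets=onsets, low_confidence=False)
    if frac < coverage_frac:
        result["pattern"] = "partial"
        return result
    times = np.array(list(onsets.values()))
    if np.ptp(times) <= sync_tol:
        result["pattern"] = "synchronous"
        return result
    pos = np.array([centroids[k] for k in onsets], dtype=np.float64)
    A = np.column_stack([np.ones_like(times), pos])
    coef, *_ = np.linalg.lstsq(A, times, rcond=None)
    grad = coef[1:]
    gnorm = float(np.hypot(*grad))
    if gnorm > 0:
        proj = pos @ (grad / gnorm)
        if np.ptp(proj) > 0:
            r = float(np.corrcoef(proj, times)[0, 1])
            if abs(r) >= corr_min:
                result["pattern"] = "propagating"
                result["axis"] = (grad / gnorm).tolist()
                result["r"] = r
                return result
    result["pattern"] = "synchronous"
    result["low_confidence"] = True
    return result
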