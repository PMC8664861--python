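"""Event detection and classification on dF/F traces.

Voltage deflections (negative-going for an ArcLight-convention sensor) and
calcium transients (positive-going) are detected by a threshold in units of
the baseline SD, then paired across channels to label events as spiking,
subthreshold, or calcium-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .traces import Trace

__all__ = [
    "Event",
    "EventTable",
    "robust_sd",
    "detect_voltage_events",
    "detect_calcium_transients",
    "classify_events",
    "peak_latency",
    "prestim_area",
    "detect_interictal_events",
    "preictal_window_stats",
    "count_peaks",
]


@dataclass
class Event:
    roi: str
    onset: float
    peak_time: float
    amplitude: float  # signed dF/F fraction at the peak
    area: float  # signed integral of dF/F over the event span (dF/F * s)
    label: str = ""  # spiking | subthreshold | calcium-only | ""
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.peak_time < self.onset:
            raise ValueError("peak_time must be >= onset")


@dataclass
class EventTable:
    events: list[Event] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events.sort(key=lambda e: (e.roi, e.onset))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def to_frame(self) -> pd.DataFrame:
        cols = ["roi", "onset_s", "peak_s", "amplitude", "area", "label", "evidence"]
        rows = [
            (e.roi, e.onset, e.peak_time, e.amplitude, e.area, e.label, e.evidence)
            for e in self.events
        ]
        return pd.DataFrame(rows, columns=cols)


def robust_sd(y: np.ndarray) -> float:
    """Median-absolute-deviation estimate of the baseline SD (robust to the
    events themselves, invariant to multiplicative gain)."""
    y = np.asarray(y, dtype=np.float64)
    return 1.4826 * float(np.median(np.abs(y - np.median(y))))


def _detect_threshold_events(
    trace: Trace, threshold_sd: float, min_dur: float, direction: int, roi: str,
    evidence: str,
) -> EventTable:
    y = trace.y * direction  # fold so excursions of interest are positive
    base = np.median(y)
    sd = robust_sd(y)
    if sd == 0:
        raise ValueError("baseline SD is zero; cannot set a threshold")
    thr = base + threshold_sd * sd
    above = y > thr
    rate = trace.rate
    min_len = max(1, int(round(min_dur * rate)))
    events = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start < min_len:
            continue
        # a long suprathreshold stretch may hold several overlapping events:
        # split it at the dips between prominent sub-peaks; the prominence
        # floor scales with the excursion so noise riding on one large event
        # does not shatter it
        seg_folded = y[start:stop]
        prom = max(1.5 * sd, 0.25 * (float(seg_folded.max()) - thr))
        pks, _ = find_peaks(seg_folded, prominence=prom, distance=min_len)
        cuts = [0]
        for p0, p1 in zip(pks, pks[1:]):
            cuts.append(p0 + int(np.argmin(seg_folded[p0:p1])))
        cuts.append(stop - start)
        for c0, c1 in zip(cuts, cuts[1:]):
            if c1 - c0 < min_len:
                continue
            s0, s1 = start + c0, start + c1
            seg = trace.y[s0:s1]
            ipk = s0 + (np.argmin(seg) if direction < 0 else np.argmax(seg))
            area = float(np.trapezoid(seg, trace.t[s0:s1]))
            events.append(Event(roi=roi, onset=float(trace.t[s0]),
                                peak_time=float(trace.t[ipk]),
                                amplitude=float(trace.y[ipk]), area=area,
                                evidence=evidence))
    cfg = dict(threshold_sd=threshold_sd, min_dur=min_dur, direction=direction,
               baseline_sd=sd)
    return EventTable(events, config=cfg)


def detect_voltage_events(
    dff: Trace, threshold_sd: float = 3.0, min_dur: float = 0.1, polarity: int = -1
) -> EventTable:
    """Detect depolarising deflections in a detrended voltage dF/F trace.

    Contiguous excursions beyond ``threshold_sd`` baseline SDs in the
    depolarising direction (negative dF/F for polarity -1) lasting at least
    ``min_dur`` seconds become events; onset is the first threshold crossing.
    """
    roi = dff.label or "roi"
    return _detect_threshold_events(dff, threshold_sd, min_dur, int(polarity), roi,
                                    evidence="voltage")


def detect_calcium_transients(
    dff: Trace, threshold_sd: float = 3.0, min_dur: float = 0.1
) -> EventTable:
    """Detect positive-going calcium transients (same rule as voltage events,
    opposite polarity)."""
    roi = dff.label or "roi"
    return _detect_threshold_events(dff, threshold_sd, min_dur, +1, roi,
                                    evidence="calcium")


def classify_events(
    volt: EventTable, ca: EventTable, coincidence: float = 0.2
) -> EventTable:
    """Label voltage events by calcium coincidence.

    A voltage event with a calcium onset within ``coincidence`` seconds of its
    [onset, peak] span is ``spiking``; one without is ``subthreshold``; a
    calcium transient with no voltage partner is ``calcium-only`` (an anomaly
    under the generative model, so it measures the detector miss rate).
    """
    rois_v = {e.roi for e in volt.events}
    rois_c = {e.roi for e in ca.events}
    if rois_v and rois_c and rois_v != rois_c and not (rois_v & rois_c):
        raise ValueError("voltage and calcium tables come from different ROIs")
    out: list[Event] = []
    used_ca: set[int] = set()
    for ev in volt.events:
        lo, hi = ev.onset - coincidence, ev.peak_time + coincidence
        match = None
        for i, ec in enumerate(ca.events):
            if i in used_ca or ec.roi != ev.roi:
                continue
            if lo <= ec.onset <= hi:
                match = i
                break
        label = "spiking" if match is not None else "subthreshold"
        if match is not None:
            used_ca.add(match)
        out.append(Event(ev.roi, ev.onset, ev.peak_time, ev.amplitude, ev.area,
                         label=label,
                         evidence="voltage+calcium" if match is not None else "voltage"))
    for i, ec in enumerate(ca.events):
        if i not in used_ca:
            out.append(Event(ec.roi, ec.onset, ec.peak_time, ec.amplitude, ec.area,
                             label="calcium-only", evidence="calcium"))
    cfg = dict(coincidence=coincidence, volt=volt.config, ca=ca.config)
    return EventTable(out, config=cfg)


def peak_latency(sta: Trace, stim_time: float = 0.0, polarity: int = -1,
                 noise_floor_sd: float = 4.0) -> float | None:
    """Latency from stimulus to the extremum of a stimulus-triggered average.

    Returns ``None`` (flagged undefined) when no extremum rises above
    ``noise_floor_sd`` pre-stimulus SDs.
    """
    pre = sta.y[sta.t < stim_time]
    post_sel = sta.t >= stim_time
    post = sta.y[post_sel]
    if post.size == 0:
        raise ValueError("STA window does not cover the post-stimulus period")
    folded = post * polarity
    ref = np.median(pre * polarity) if pre.size else np.median(folded)
    sd = robust_sd(pre) if pre.size >= 3 else robust_sd(sta.y)
    ipk = int(np.argmax(folded))
    if sd > 0 and folded[ipk] - ref < noise_floor_sd * sd:
        return None
    return float(sta.t[post_sel][ipk] - stim_time)


def prestim_area(dff: Trace, stim_time: float, window: float = 0.5) -> float:
    """Signed integral of dF/F over [stim - window, stim] (dF/F * s)."""
    lo = stim_time - window
    if lo < dff.t[0] - 1e-9 or stim_time > dff.t[-1] + 1e-9:
        raise ValueError("pre-stimulus window escapes the trace")
    sel = (dff.t >= lo) & (dff.t <= stim_time)
    return float(np.trapezoid(dff.y[sel], dff.t[sel]))


def detect_interictal_events(
    sig: Trace, threshold_sd: float = 3.0, refractory: float = 0.5, direction: int = 0,
    min_width: int = 1,
) -> tuple[EventTable, float]:
    """Detect sharp interictal deflections and report their rate.

    ``direction`` 0 detects deflections of either sign (|deviation| from the
    median); -1/+1 restrict to one polarity.  Peaks closer than ``refractory``
    seconds collapse into one event; ``min_width`` (samples) rejects
    single-sample noise spikes.  Returns the table and events/s.
    """
    if sig.t.size < 2:
        raise ValueError("zero-duration input")
    y = sig.y - np.median(sig.y)
    folded = np.abs(y) if direction == 0 else y * direction
    sd = robust_sd(sig.y)
    if sd == 0:
        return EventTable([], config=dict(threshold_sd=threshold_sd)), 0.0
    rate = sig.rate
    peaks, props = find_peaks(folded, height=threshold_sd * sd,
                              distance=max(1, int(round(refractory * rate))),
                              width=min_width if min_width > 1 else None)
    roi = sig.label or "signal"
    events = [
        Event(roi=roi, onset=float(sig.t[p]), peak_time=float(sig.t[p]),
              amplitude=float(y[p]), area=0.0, evidence=sig.kind)
        for p in peaks
    ]
    duration = sig.duration
    cfg = dict(threshold_sd=threshold_sd, refractory=refractory, direction=direction,
               baseline_sd=sd)
    return EventTable(events, config=cfg), len(events) / duration


def preictal_window_stats(
    table: EventTable, seizure_onset: float,
    windows: tuple[tuple[float, float], ...] = ((0.0, 10.0), (10.0, 20.0)),
) -> list[dict]:
    """Partition events into look-back windows before seizure onset.

    ``windows`` are (lo, hi) in seconds before onset and must not overlap.
    Each entry reports the count and mean |amplitude| (None when empty).
    """
    spans = sorted(windows)
    for (a_lo, a_hi), (b_lo, b_hi) in zip(spans, spans[1:]):
        if b_lo < a_hi:
            raise ValueError("look-back windows overlap")
    out = []
    for lo, hi in windows:
        sel = [e for e in table.events
               if lo <= seizure_onset - e.onset < hi]
        amps = [abs(e.amplitude) for e in sel]
        out.append(dict(window=(lo, hi), count=len(sel),
                        mean_abs_amplitude=float(np.mean(amps)) if amps else None))
    return out


def count_peaks(trace: Trace, min_height: float, min_separation: float) -> tuple[int, float]:
    """Count local maxima above ``min_height`` (relative to the trace median),
    at least ``min_separation`` seconds apart.  Returns (count, peaks/min)."""
    y = trace.y - np.median(trace.y)
    peaks, _ = find_peaks(y, height=min_height,
                          distance=max(1, int(round(min_separation * trace.rate))))
    per_min = len(peaks) / trace.duration * 60.0
    return len(peaks), per_min
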