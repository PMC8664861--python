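"""ROI/grid/whole-FOV trace extraction and core trace statistics.

Fluorescence change is stored as a dimensionless fraction internally and
rendered as percent only in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import LSQUnivariateSpline

from .preprocess import FrameStack

__all__ = [
    "ROISet",
    "Trace",
    "TraceSet",
    "partition_fov",
    "extract_traces",
    "detrend",
    "compute_dff",
    "compute_dff_spontaneous",
    "compute_snr",
    "stimulus_triggered_average",
]

FULL_FOV_LABEL = "full-fov"


@dataclass
class Trace:
    """A uniformly sampled time series with provenance.

    ``kind`` is one of ``raw``, ``detrended``, ``dff``, ``electrical``.
    """

    t: np.ndarray
    y: np.ndarray
    kind: str = "raw"
    label: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.t.shape != self.y.shape:
            raise ValueError("t and y must have equal length")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("t must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("t must be uniformly sampled")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y contains non-finite values")

    @property
    def rate(self) -> float:
        if self.t.size < 2:
            raise ValueError("rate undefined for a single sample")
        return 1.0 / (self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return self.t[-1] - self.t[0] + 1.0 / self.rate

    def copy(self) -> "Trace":
        return Trace(self.t.copy(), self.y.copy(), self.kind, self.label)


@dataclass
class TraceSet:
    """An ordered collection of traces sharing one time base."""

    traces: list[Trace] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.traces) > 1:
            t0 = self.traces[0].t
            for tr in self.traces[1:]:
                if tr.t.shape != t0.shape or not np.allclose(tr.t, t0):
                    raise ValueError("traces do not share a time base")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    def __getitem__(self, label: str) -> Trace:
        for tr in self.traces:
            if tr.label == label:
                return tr
        raise KeyError(label)

    @property
    def labels(self) -> list[str]:
        return [tr.label for tr in self.traces]

    @property
    def t(self) -> np.ndarray:
        return self.traces[0].t

    def as_matrix(self) -> np.ndarray:
        return np.stack([tr.y for tr in self.traces])


@dataclass
class ROISet:
    """Pixel masks with labels and centroids (in micrometres)."""

    masks: list[np.ndarray]
    labels: list[str]
    centroids: np.ndarray  # (n, 2) in um, (x, y)
    kind: str = "soma"

    def __post_init__(self) -> None:
        if not (len(self.masks) == len(self.labels) == len(self.centroids)):
            raise ValueError("masks, labels and centroids must align")
        for m in self.masks:
            if not np.any(m):
                raise ValueError("empty ROI mask")
        self.centroids = np.asarray(self.centroids, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.masks)


def partition_fov(
    shape: tuple[int, int], n_rows: int, n_cols: int, pixel_size: float = 1.0
) -> ROISet:
    """Partition an H x W field into a grid of rectangular ROIs plus one
    full-FOV ROI (appended last, labelled ``full-fov``).

    Masks are disjoint and exhaustive; when the image dimension is not an
    exact multiple of the grid, block sizes differ by at most one pixel.
    """
    H, W = shape
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid must be at least 1 x 1")
    if n_rows > H or n_cols > W:
        raise ValueError("grid larger than image")
    row_edges = np.linspace(0, H, n_rows + 1).round().astype(int)
    col_edges = np.linspace(0, W, n_cols + 1).round().astype(int)
    masks, labels, cents = [], [], []
    for i in range(n_rows):
        for j in range(n_cols):
            m = np.zeros((H, W), dtype=bool)
            m[row_edges[i]: row_edges[i + 1], col_edges[j]: col_edges[j + 1]] = True
            masks.append(m)
            labels.append(f"grid_{i}_{j}")
            cy = (row_edges[i] + row_edges[i + 1] - 1) / 2.0
            cx = (col_edges[j] + col_edges[j + 1] - 1) / 2.0
            cents.append((cx * pixel_size, cy * pixel_size))
    full = np.ones((H, W), dtype=bool)
    masks.append(full)
    labels.append(FULL_FOV_LABEL)
    cents.append(((W - 1) / 2.0 * pixel_size, (H - 1) / 2.0 * pixel_size))
    return ROISet(masks, labels, np.array(cents), kind="grid-cell")


def extract_traces(stack: FrameStack, rois: ROISet) -> TraceSet:
    """Per-frame mean fluorescence over each ROI mask."""
    data = stack.data.astype(np.float64, copy=False)
    t = stack.times
    out = []
    for mask, label in zip(rois.masks, rois.labels):
        if mask.shape != data.shape[1:]:
            raise ValueError(f"mask shape {mask.shape} does not match frames")
        y = data[:, mask].mean(axis=1)
        out.append(Trace(t, y, kind="raw", label=label))
    return TraceSet(out)


def _spline_trend(t: np.ndarray, y: np.ndarray, knot_spacing: float) -> np.ndarray:
    if t[-1] - t[0] < 2 * knot_spacing:
        raise ValueError("trace shorter than 2 x knot_spacing")
    # odd (point) reflection at each end: continues the local slope, so the
    # cubic spline neither kinks at the boundary nor flexes into transients
    # near the trace edges (a reflected transient is inverted and its pull on
    # the trend cancels)
    dt = t[1] - t[0]
    n_pad = min(int(round(knot_spacing / dt)), t.size - 1)
    t_pad = np.concatenate([t[0] - dt * np.arange(n_pad, 0, -1), t,
                            t[-1] + dt * np.arange(1, n_pad + 1)])
    y_pad = np.concatenate([2 * y[0] - y[n_pad:0:-1], y,
                            2 * y[-1] - y[-2:-n_pad - 2:-1]])
    knots = np.arange(t_pad[0] + knot_spacing, t_pad[-1] - 1e-9, knot_spacing)
    spl = LSQUnivariateSpline(t_pad, y_pad, knots, k=3)
    return spl(t)


def detrend(trace: Trace, knot_spacing: float = 10.0) -> Trace:
    """Subtract a slow smoothing-spline trendline, re-adding the mean.

    The spline has knots every ``knot_spacing`` seconds, so oscillations much
    faster than the knot spacing pass through unattenuated while drift and
    photobleaching are removed.
    """
    trend = _spline_trend(trace.t, trace.y, knot_spacing)
    # adding back mean(trend) keeps the output mean exactly equal to the input mean
    y = trace.y - trend + trend.mean()
    return Trace(trace.t, y, kind="detrended", label=trace.label)


def compute_dff(trace: Trace, f0_window: tuple[float, float]) -> Trace:
    """(F - F0)/F0 with F0 the mean over ``f0_window`` (seconds)."""
    lo, hi = f0_window
    sel = (trace.t >= lo) & (trace.t < hi)
    if not np.any(sel):
        raise ValueError("F0 window outside trace")
    f0 = trace.y[sel].mean()
    if abs(f0) < 1e-12:
        raise ValueError("F0 is zero; cannot normalise")
    return Trace(trace.t, (trace.y - f0) / f0, kind="dff", label=trace.label)


def compute_dff_spontaneous(trace: Trace, knot_spacing: float = 10.0) -> Trace:
    """dF/F for stimulus-free segments: F0 is the local spline trend, so the
    output is the fractional fluctuation about the slow trendline."""
    trend = _spline_trend(trace.t, trace.y, knot_spacing)
    if np.any(np.abs(trend) < 1e-12):
        raise ValueError("trend passes through zero; cannot normalise")
    return Trace(trace.t, (trace.y - trend) / trend, kind="dff", label=trace.label)


def compute_snr(
    dff: Trace,
    stim_time: float,
    baseline: float = 0.5,
    response_window: float = 1.0,
    polarity: str = "min",
) -> float:
    """Peak dF/F over the SD of the pre-stimulus baseline fluctuation.

    ``polarity`` selects the extremum searched post-stimulus: ``"min"`` for a
    negative-going voltage channel, ``"max"`` for calcium.
    """
    base = dff.y[(dff.t >= stim_time - baseline) & (dff.t < stim_time)]
    if base.size < 2:
        raise ValueError("baseline window outside trace")
    sd = base.std(ddof=1)
    if sd == 0:
        raise ValueError("baseline SD is zero")
    resp = dff.y[(dff.t >= stim_time) & (dff.t <= stim_time + response_window)]
    if resp.size == 0:
        raise ValueError("response window outside trace")
    peak = resp.min() if polarity == "min" else resp.max()
    return abs(peak) / sd


def stimulus_triggered_average(
    dff: Trace, stim_times, window: tuple[float, float] = (0.5, 1.0)
) -> tuple[Trace, np.ndarray]:
    """Align trials at each stimulus and average pointwise.

    ``window = (pre, post)`` in seconds; the returned mean trace has a time
    axis relative to the stimulus.  Also returns the (n_trials, n_samples)
    trial matrix.
    """
    pre, post = window
    rate = dff.rate
    n_pre = int(round(pre * rate))
    n_post = int(round(post * rate))
    rows = []
    for s in np.atleast_1d(stim_times):
        i = int(round((s - dff.t[0]) * rate))
        if i - n_pre < 0 or i + n_post >= dff.y.size:
            raise ValueError(f"window around stimulus at {s} s escapes trace")
        rows.append(dff.y[i - n_pre: i + n_post + 1])
    mat = np.stack(rows)
    rel_t = (np.arange(-n_pre, n_post + 1)) / rate
    mean = Trace(rel_t, mat.mean(axis=0), kind=dff.kind, label=dff.label + "|sta")
    return mean, mat
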