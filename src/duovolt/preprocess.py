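"""Movie preprocessing: stimulus-artifact frame replacement, rigid motion
correction, and per-pixel temporal Kalman filtering.

All operations accept and return :class:`FrameStack` objects and never modify
their input in place.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

log = logging.getLogger(__name__)

__all__ = [
    "FrameStack",
    "KalmanParams",
    "replace_stimulus_frames",
    "register_rigid",
    "kalman_stack_filter",
]


@dataclass
class FrameStack:
    """One channel's movie: a T x H x W intensity grid.

    Parameters
    ----------
    data : ndarray, shape (T, H, W)
        Non-negative, finite intensities.
    frame_rate : float
        Frames per second, > 0.
    channel : str
        ``"voltage"`` or ``"calcium"``.
    origin : str
        Provenance string (file path or generating stage).
    """

    data: np.ndarray
    frame_rate: float
    channel: str = "voltage"
    origin: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected T x H x W data, got shape {self.data.shape}")
        if self.data.shape[0] < 1:
            raise ValueError("stack must contain at least one frame")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def times(self) -> np.ndarray:
        """Frame start times in seconds (frame k spans [k/rate, (k+1)/rate))."""
        return np.arange(self.n_frames) / self.frame_rate

    def copy(self) -> "FrameStack":
        return replace(self, data=self.data.copy())


@dataclass(frozen=True)
class KalmanParams:
    """Temporal Kalman stack-filter settings.

    ``gain`` is the bias placed on the prediction, ``noise_var`` the acquisition
    noise variance estimate.  Defaults (0.80, 0.05) are the reference settings.
    """

    gain: float = 0.80
    noise_var: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.gain < 1.0):
            raise ValueError("gain must lie in [0, 1)")
        if not self.noise_var > 0:
            raise ValueError("noise_var must be > 0")


def replace_stimulus_frames(stack: FrameStack, flash_frames) -> FrameStack:
    """Replace stimulus-artifact frames with their predecessor.

    Each listed frame becomes an exact copy of the frame before it, applied in
    ascending index order so a run of consecutive flash frames all copy the
    last clean frame.  A flash frame at index 0 has no predecessor and is
    replaced by the next clean frame instead.
    """
    idx = sorted(int(i) for i in np.atleast_1d(np.asarray(flash_frames, dtype=int)).ravel()) \
        if np.size(flash_frames) else []
    out = stack.data.copy()
    T = stack.n_frames
    for i in idx:
        if not (0 <= i < T):
            raise IndexError(f"flash frame {i} outside [0, {T})")
    flagged = set(idx)
    for i in idx:
        if i > 0:
            out[i] = out[i - 1]
        else:
            # no predecessor: borrow the first clean frame after the run
            j = 1
            while j in flagged and j < T - 1:
                j += 1
            out[0] = stack.data[j]
    return replace(stack, data=out, origin=stack.origin + "|deflashed")


def register_rigid(
    stack: FrameStack,
    reference: str = "mean-frame",
    max_shift: float = 15.0,
    upsample_factor: int = 10,
) -> tuple[FrameStack, np.ndarray]:
    """Rigid translation registration via phase cross-correlation.

    Each frame is translated to best match the reference image; borders exposed
    by the shift are filled with the frame median.  Returns the registered
    stack and the applied per-frame (row, col) shifts in pixels.  Shifts larger
    than ``max_shift`` are clipped (with a warning) — only plausible jitter is
    corrected, degenerate frames do not fly away.
    """
    if stack.n_frames < 2:
        raise ValueError("registration requires at least two frames")
    data = stack.data.astype(np.float64, copy=False)
    if reference == "first-frame":
        ref = data[0]
    elif reference == "mean-frame":
        ref = data.mean(axis=0)
    else:
        raise ValueError("reference must be 'first-frame' or 'mean-frame'")
    if np.ptp(ref) == 0:
        raise ValueError("degenerate (constant) reference frame")

    # estimate shifts on lightly smoothed copies (shot noise otherwise limits
    # subpixel accuracy); apply them to the raw frames
    ref_s = ndimage.gaussian_filter(ref, 1.0)
    shifts = np.zeros((stack.n_frames, 2))
    out = np.empty_like(data)
    clipped = False
    for k in range(stack.n_frames):
        sh, _, _ = phase_cross_correlation(
            ref_s, ndimage.gaussian_filter(data[k], 1.0),
            upsample_factor=upsample_factor, normalization=None)
        if np.any(np.abs(sh) > max_shift):
            clipped = True
            sh = np.clip(sh, -max_shift, max_shift)
        shifts[k] = sh
        if np.allclose(sh, 0):
            out[k] = data[k]
        else:
            out[k] = ndimage.shift(
                data[k], sh, order=1, mode="constant", cval=float(np.median(data[k]))
            )
    if clipped:
        warnings.warn(
            f"registration shifts exceeded max_shift={max_shift} px and were clipped",
            RuntimeWarning,
            stacklevel=2,
        )
    return replace(stack, data=out, origin=stack.origin + "|registered"), shifts


def apply_shifts(stack: FrameStack, shifts: np.ndarray) -> FrameStack:
    """Apply precomputed per-frame (row, col) shifts (e.g. the shifts
    recovered from a simultaneously acquired channel)."""
    if shifts.shape != (stack.n_frames, 2):
        raise ValueError("one (row, col) shift per frame required")
    data = stack.data.astype(np.float64, copy=False)
    out = np.empty_like(data)
    for k in range(stack.n_frames):
        if np.allclose(shifts[k], 0):
            out[k] = data[k]
        else:
            out[k] = ndimage.shift(data[k], shifts[k], order=1, mode="constant",
                                   cval=float(np.median(data[k])))
    return replace(stack, data=out, origin=stack.origin + "|registered")


def kalman_scalar_oracle(series, gain: float, noise_var: float) -> np.ndarray:
    """Reference per-pixel scalar recursion (pure Python, one pixel series).

    Kept deliberately independent of :func:`kalman_stack_filter`; the
    vectorised filter must reproduce it bitwise.
    """
    x = [float(v) for v in series]
    out = [x[0]]
    est = x[0]
    var = noise_var
    for obs in x[1:]:
        pred = est
        K = var / (var + noise_var)
        est = gain * pred + (1.0 - gain) * obs + K * (obs - pred)
        var = var * (1.0 - K)
        out.append(est)
    return np.array(out, dtype=np.float64)


def kalman_stack_filter(stack: FrameStack, p: KalmanParams | None = None) -> FrameStack:
    """Per-pixel recursive temporal Kalman filter.

    State is initialised to frame 0 with predicted variance ``noise_var``.  At
    each subsequent frame::

        K   = var / (var + noise_var)
        est = gain * pred + (1 - gain) * obs + K * (obs - pred)
        var = var * (1 - K)

    Output frame ``t`` is the estimate after observing frame ``t``; frame 0
    passes through unchanged.  The arithmetic matches the scalar per-pixel
    recursion exactly (same operation order, float64).
    """
    if p is None:
        p = KalmanParams()
    if stack.n_frames < 2:
        raise ValueError("kalman filter requires at least two frames")
    data = stack.data.astype(np.float64, copy=False)
    out = np.empty_like(data)
    out[0] = data[0]
    est = data[0].copy()
    var = np.full(data.shape[1:], p.noise_var, dtype=np.float64)
    for t in range(1, data.shape[0]):
        obs = data[t]
        pred = est
        K = var / (var + p.noise_var)
        est = p.gain * pred + (1.0 - p.gain) * obs + K * (obs - pred)
        var = var * (1.0 - K)
        out[t] = est
    return replace(stack, data=out, origin=stack.origin + "|kalman")
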