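"""Synthetic dual-channel imaging data.

Generates membrane-voltage and spike dynamics for a small cortical population,
passes them through indicator forward models (a sigmoidal voltage sensor and a
spike-number-linear calcium sensor), and renders seeded dual-channel movies
plus an LFP trace and full ground truth, so that every analysis stage can be
verified against known inputs.

All membrane-voltage dynamics are simulated at 1 kHz; rendering integrates to
the imaging frame rate by box averaging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .preprocess import FrameStack
from .traces import Trace

__all__ = [
    "SensorModel",
    "CalciumModel",
    "VoltageDynamics",
    "SeizureConfig",
    "ScenePlan",
    "NoiseModel",
    "GroundTruth",
    "VoltagePopulation",
    "SeizureEpisode",
    "default_sensor",
    "default_calcium",
    "default_scene",
    "simulate_population_voltage",
    "simulate_seizure_episode",
    "sensor_fluorescence",
    "calcium_fluorescence",
    "render_dual_channel_movie",
    "synthesize_lfp",
]

VM_RATE = 1000.0  # Hz, internal voltage sampling rate

# rise time constant of the generic depolarising-event kernel (UP state, EPSP,
# evoked potential); the decay constant is event duration / 3
EVENT_RISE_TAU = 0.02

# conduction speed of the fast subthreshold (synaptic barrage) pathway, used
# for IIS coupling and ictal subthreshold arrival; much faster than the ictal
# recruitment wavefront
SUBTHRESHOLD_SPEED = 20000.0  # um/s

DIGITAL_GAIN = 10000.0  # counts per fluorescence unit when shot noise is off
FULL_SCALE = np.iinfo(np.uint16).max


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensorModel:
    """Voltage-indicator transfer function.

    Steady state follows a Boltzmann sigmoid of membrane potential; ``polarity``
    -1 means fluorescence decreases on depolarisation.  Kinetics are a
    two-exponential low-pass (fast/slow components); photobleaching is a
    multiplicative exponential decay.  ``targeting='null'`` models a control
    indicator with no voltage sensitivity (df_max forced to 0).
    """

    v_half: float = -30.0
    k_slope: float = 25.0
    df_max: float = 0.32
    polarity: int = -1
    tau_fast: float = 0.060
    tau_slow: float = 0.300
    frac_fast: float = 0.7
    tau_bleach: float = 1200.0
    targeting: str = "somatic"

    def __post_init__(self) -> None:
        if self.k_slope <= 0:
            raise ValueError("k_slope must be > 0")
        if not (0.0 <= self.frac_fast <= 1.0):
            raise ValueError("frac_fast must lie in [0, 1]")
        if self.tau_fast > self.tau_slow:
            raise ValueError("tau_fast must not exceed tau_slow")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be -1 or +1")
        if self.targeting not in ("somatic", "pan-cellular", "null"):
            raise ValueError("unknown targeting")
        if self.targeting == "null" and self.df_max != 0.0:
            object.__setattr__(self, "df_max", 0.0)

    def steady_state(self, vm) -> np.ndarray:
        """Steady-state fluorescence for membrane potential ``vm`` (mV).

        F(V) = 1 + df_max * polarity * sigma(V), with sigma the increasing
        logistic of midpoint ``v_half`` and steepness ``k_slope``, so that
        polarity -1 yields fluorescence monotonically decreasing in V.
        """
        vm = np.asarray(vm, dtype=np.float64)
        sig = 1.0 / (1.0 + np.exp(-(vm - self.v_half) / self.k_slope))
        return 1.0 + self.df_max * self.polarity * sig

    def slope_at(self, v: float) -> float:
        """Local sensitivity d(dF/F)/dV at ``v``, in %dF/F per mV.

        Normalised by the steady-state fluorescence at ``v``.
        """
        e = math.exp(-(v - self.v_half) / self.k_slope)
        dsig = e / (self.k_slope * (1.0 + e) ** 2)
        f = float(self.steady_state(v))
        return 100.0 * self.df_max * self.polarity * dsig / f


@dataclass(frozen=True)
class CalciumModel:
    """Spike-number-linear calcium indicator.

    Each spike adds a double-exponential transient of fractional amplitude
    ``a_spike``; ``subthreshold_gain`` (default 0) couples residual membrane
    potential into the calcium channel.
    """

    a_spike: float = 0.15
    tau_rise: float = 0.020
    tau_decay: float = 0.400
    subthreshold_gain: float = 0.0

    def __post_init__(self) -> None:
        if self.a_spike < 0:
            raise ValueError("a_spike must be >= 0")
        if not self.tau_rise < self.tau_decay:
            raise ValueError("tau_rise must be < tau_decay")

    @property
    def peak_delay(self) -> float:
        """Time from spike to transient peak (closed form for the kernel)."""
        r, d = self.tau_rise, self.tau_decay
        return r * d / (d - r) * math.log(d / r)


@dataclass(frozen=True)
class VoltageDynamics:
    """Parameters of spontaneous/evoked membrane-potential activity."""

    v_rest: float = -68.5
    up_rate: float = 0.15
    up_amp: float = 22.0
    up_dur: float = 0.8
    epsp_rate: float = 0.3
    epsp_amp: float = 4.0
    evoked_latency: float = 0.04
    evoked_amp: float = 22.0
    spike_threshold: float = -40.0
    spike_prob_per_up: float = 0.4

    def __post_init__(self) -> None:
        if self.up_amp <= 0:
            raise ValueError("up_amp must be > 0")
        if self.evoked_latency < 0:
            raise ValueError("evoked_latency must be >= 0")
        if self.spike_threshold <= self.v_rest:
            raise ValueError("spike_threshold must exceed v_rest")
        for name in ("v_rest", "up_rate", "up_amp", "up_dur", "epsp_rate",
                     "epsp_amp", "evoked_latency", "evoked_amp",
                     "spike_threshold", "spike_prob_per_up"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} is not finite")


@dataclass(frozen=True)
class SeizureConfig:
    """Focal-seizure scenario: a distant focus with pre-ictal interictal
    barrages and a slowly propagating ictal wavefront."""

    focus_offset: float = 1000.0
    wavefront_speed: float = 100.0
    preictal_window: float = 40.0
    iis_rate_early: float = 0.4
    iis_rate_late: float = 1.0
    iis_coupling_ramp: float = 0.03
    ictal_sync_jitter: float = 0.05
    iis_amp: float = 18.0
    ictal_amp: float = 18.0

    def __post_init__(self) -> None:
        if self.wavefront_speed <= 0:
            raise ValueError("wavefront_speed must be > 0")
        if self.iis_rate_late < self.iis_rate_early:
            raise ValueError("iis_rate_late must be >= iis_rate_early")
        if not (0.0 <= self.iis_coupling_ramp <= 1.0):
            raise ValueError("iis_coupling_ramp must lie in [0, 1]")


@dataclass(frozen=True)
class ScenePlan:
    """Geometry of the imaged field: cell positions (um), soma radius,
    neuropil level, field of view and pixel size."""

    cell_positions: np.ndarray  # (n, 2) in um, (x, y)
    soma_radius: float = 10.0
    neuropil_level: float = 0.3
    fov: tuple[float, float] = (128.0, 128.0)
    pixel_size: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "cell_positions",
            np.atleast_2d(np.asarray(self.cell_positions, dtype=np.float64)),
        )
        if self.soma_radius <= 0 or self.pixel_size <= 0:
            raise ValueError("soma_radius and pixel_size must be > 0")
        w, h = self.fov
        p = self.cell_positions
        if np.any(p[:, 0] < 0) or np.any(p[:, 0] > w) or np.any(p[:, 1] < 0) or np.any(p[:, 1] > h):
            raise ValueError("all cells must lie inside the field of view")

    @property
    def n_cells(self) -> int:
        return self.cell_positions.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        w, h = self.fov
        return int(round(h / self.pixel_size)), int(round(w / self.pixel_size))

    def cell_masks(self) -> list[np.ndarray]:
        H, W = self.shape
        yy, xx = np.mgrid[0:H, 0:W]
        xs = (xx + 0.5) * self.pixel_size
        ys = (yy + 0.5) * self.pixel_size
        masks = []
        for cx, cy in self.cell_positions:
            masks.append((xs - cx) ** 2 + (ys - cy) ** 2 <= self.soma_radius**2)
        return masks


@dataclass(frozen=True)
class NoiseModel:
    """Acquisition artifacts: heartbeat gain, shot noise, motion jitter, and
    stimulus flash frames."""

    heartbeat_freq: float = 7.0
    heartbeat_amp: float = 0.01
    photon_scale: float = 2000.0
    motion_sd: float = 0.3
    flash_frames: tuple[int, ...] = ()
    psf_sigma: float = 1.0  # optical blur in pixels; keeps cell edges band-limited

    def __post_init__(self) -> None:
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")
        if min(self.heartbeat_amp, self.photon_scale, self.motion_sd) < 0:
            raise ValueError("noise amplitudes must be >= 0")
        object.__setattr__(self, "flash_frames", tuple(int(i) for i in self.flash_frames))


@dataclass
class GroundTruth:
    """Everything the simulator knows: spike times, true events, motion,
    voltage traces, seizure markers."""

    spike_times: list[np.ndarray]
    events: list[dict]  # roi, onset, peak_time, amplitude_mv, kind, spiking
    vm: np.ndarray  # (n_cells, n) mV at 1 kHz
    motion: np.ndarray | None = None  # (T, 2) pixels
    lfp_onset: float | None = None
    recruitment_times: np.ndarray | None = None
    subthreshold_onsets: np.ndarray | None = None

    def __post_init__(self) -> None:
        for st in self.spike_times:
            if st.size > 1 and np.any(np.diff(st) <= 0):
                raise ValueError("spike times must be strictly increasing per cell")
        if self.lfp_onset is not None and self.recruitment_times is not None:
            if np.any(self.recruitment_times < self.lfp_onset):
                raise ValueError("recruitment times must be >= lfp_onset")


@dataclass
class VoltagePopulation:
    """Output of a voltage simulation: 1 kHz traces plus true events."""

    t: np.ndarray
    vm: np.ndarray  # (n_cells, n)
    spike_times: list[np.ndarray]
    events: list[dict]

    @property
    def n_cells(self) -> int:
        return self.vm.shape[0]


@dataclass
class SeizureEpisode:
    population: VoltagePopulation
    focus_vm: np.ndarray  # (1, n) mV at the initiation site
    iis_times: np.ndarray
    iis_coupling: np.ndarray
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# defaults
# ---------------------------------------------------------------------------

def default_sensor(variant: str = "st") -> SensorModel:
    """Built-in sensor configurations.

    ``st``  soma-targeted fast variant (more negative midpoint, higher
            sensitivity at rest), ``mt`` the parent variant, ``pan`` the
            untargeted fast variant, ``null`` a voltage-insensitive control.
    """
    if variant == "st":
        return SensorModel()
    if variant == "mt":
        return SensorModel(v_half=-10.0)
    if variant == "pan":
        return SensorModel(targeting="pan-cellular")
    if variant == "null":
        return SensorModel(df_max=0.0, targeting="null")
    raise ValueError(f"unknown sensor variant {variant!r}")


def default_calcium() -> CalciumModel:
    return CalciumModel()


def default_scene(n_cells: int = 20, fov: tuple[float, float] = (128.0, 128.0),
                  pixel_size: float = 2.0, soma_radius: float = 6.0,
                  neuropil_level: float = 0.3, seed: int | None = None) -> ScenePlan:
    """Place cells on a jittered grid covering the field of view."""
    rng = np.random.default_rng(seed)
    w, h = fov
    n_side = int(math.ceil(math.sqrt(n_cells)))
    margin = 2.0 * soma_radius
    gx = np.linspace(margin, w - margin, n_side)
    gy = np.linspace(margin, h - margin, n_side)
    pts = np.array([(x, y) for y in gy for x in gx])[:n_cells]
    jitter = rng.uniform(-0.3, 0.3, size=pts.shape) * soma_radius
    pts = np.clip(pts + jitter, soma_radius, [w - soma_radius, h - soma_radius])
    return ScenePlan(pts, soma_radius=soma_radius, neuropil_level=neuropil_level,
                     fov=fov, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def _event_kernel(amp: float, decay_tau: float, rate: float = VM_RATE,
                  rise_tau: float = EVENT_RISE_TAU) -> np.ndarray:
    """Depolarising-event waveform: (1 - exp(-t/rise)) * exp(-t/decay),
    normalised so its peak equals ``amp``."""
    t_max = 6.0 * decay_tau + 6.0 * rise_tau
    t = np.arange(0.0, t_max, 1.0 / rate)
    k = (1.0 - np.exp(-t / rise_tau)) * np.exp(-t / decay_tau)
    return amp * k / k.max()


def event_kernel_peak_delay(decay_tau: float, rise_tau: float = EVENT_RISE_TAU) -> float:
    """Analytic location of the event-kernel maximum after onset."""
    return rise_tau * math.log(1.0 + decay_tau / rise_tau)


def _add_kernel(y: np.ndarray, onset: float, kernel: np.ndarray, rate: float = VM_RATE) -> None:
    i0 = int(round(onset * rate))
    if i0 >= y.size:
        return
    i0 = max(i0, 0)
    n = min(kernel.size, y.size - i0)
    y[i0: i0 + n] += kernel[:n]


def _kernel_crossing(amp: float, level: float, decay_tau: float,
                     rate: float = VM_RATE) -> float | None:
    """Time after onset at which the event kernel first reaches ``level``."""
    if amp < level:
        return None
    k = _event_kernel(amp, decay_tau, rate)
    idx = np.argmax(k >= level)
    if k[idx] < level:
        return None
    return idx / rate


# ---------------------------------------------------------------------------
# voltage simulation
# ---------------------------------------------------------------------------

def _poisson_times(rate: float, duration: float, rng) -> np.ndarray:
    if rate <= 0 or duration <= 0:
        return np.empty(0)
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def _event_amplitude(dyn: VoltageDynamics, base_amp: float, rng) -> tuple[float, bool]:
    """Draw one event amplitude and its spiking gate.

    A gated (spiking) event is boosted above ``spike_threshold``; an ungated
    event is capped safely below it, so whether the peak crosses threshold is
    an exact function of the returned amplitude.
    """
    span = dyn.spike_threshold - dyn.v_rest
    amp = base_amp * (1.0 + 0.15 * rng.standard_normal())
    if rng.uniform() < dyn.spike_prob_per_up:
        amp = max(amp, span + 4.0 + 2.0 * abs(rng.standard_normal()))
    else:
        amp = min(amp, 0.90 * span)
    return max(amp, 0.5), amp >= span


def simulate_population_voltage(
    dyn: VoltageDynamics,
    scene: ScenePlan,
    stim_times=(),
    duration: float = 60.0,
    seed: int | None = None,
) -> VoltagePopulation:
    """Simulate 1 kHz membrane-potential traces for every cell in the scene.

    Spontaneous UP states are population events (shared onset with small
    per-cell jitter); EPSPs are independent per cell; each stimulus evokes a
    depolarisation ``evoked_latency`` later.  Spikes are recorded whenever an
    event's peak crosses ``spike_threshold``; the gate probability
    ``spike_prob_per_up`` controls how often that happens.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    stim_times = np.sort(np.atleast_1d(np.asarray(stim_times, dtype=float))) \
        if np.size(stim_times) else np.empty(0)
    if stim_times.size and (stim_times.min() < 0 or stim_times.max() >= duration):
        raise ValueError("stimulus times must lie within [0, duration)")

    rng = np.random.default_rng(seed)
    n = int(round(duration * VM_RATE))
    t = np.arange(n) / VM_RATE
    n_cells = scene.n_cells
    vm = np.full((n_cells, n), dyn.v_rest, dtype=np.float64)
    spikes: list[list[float]] = [[] for _ in range(n_cells)]
    events: list[dict] = []
    decay_tau = max(dyn.up_dur, 1e-3) / 3.0
    peak_delay = event_kernel_peak_delay(decay_tau)

    # population events keep a refractory spacing (UP states have OFF periods);
    # evoked responses win collisions with spontaneous ones
    min_sep = 2.0
    evoked = [("evoked", s + dyn.evoked_latency, dyn.evoked_amp) for s in stim_times]
    up_onsets = []
    for o in _poisson_times(dyn.up_rate, duration, rng):
        near_evoked = any(abs(o - e[1]) < min_sep for e in evoked)
        near_up = up_onsets and o - up_onsets[-1] < min_sep
        if not near_evoked and not near_up:
            up_onsets.append(o)
    shared = [("up", o, dyn.up_amp) for o in up_onsets] + evoked

    for kind, onset, base_amp in shared:
        for c in range(n_cells):
            o = onset + (0.005 * rng.standard_normal() if kind == "up" else
                         0.003 * rng.standard_normal())
            o = max(o, 0.0)
            amp, spiking = _event_amplitude(dyn, base_amp, rng)
            _add_kernel(vm[c], o, _event_kernel(amp, decay_tau))
            if spiking:
                dt_cross = _kernel_crossing(amp, dyn.spike_threshold - dyn.v_rest, decay_tau)
                if dt_cross is not None:
                    n_sp = 1 + rng.poisson(1.0)
                    for k in range(n_sp):
                        ts = o + dt_cross + 0.015 * k
                        if ts < duration:
                            spikes[c].append(ts)
            events.append(dict(roi=f"cell_{c:03d}", onset=o, peak_time=o + peak_delay,
                               amplitude_mv=amp, kind=kind, spiking=bool(spiking)))

    # small independent EPSPs, never spiking
    epsp_tau = 0.05
    for c in range(n_cells):
        for o in _poisson_times(dyn.epsp_rate, duration, rng):
            amp = max(dyn.epsp_amp * (1.0 + 0.2 * rng.standard_normal()), 0.1)
            _add_kernel(vm[c], o, _event_kernel(amp, epsp_tau))

    spike_arr = [_strictly_increasing(np.array(sorted(s))) for s in spikes]
    events.sort(key=lambda e: (e["roi"], e["onset"]))
    return VoltagePopulation(t=t, vm=vm, spike_times=spike_arr, events=events)


def _strictly_increasing(ts: np.ndarray) -> np.ndarray:
    if ts.size < 2:
        return ts
    out = ts.copy()
    for i in range(1, out.size):
        if out[i] <= out[i - 1]:
            out[i] = out[i - 1] + 1e-4
    return out


def simulate_seizure_episode(
    dyn: VoltageDynamics,
    scene: ScenePlan,
    sz: SeizureConfig,
    duration: float = 60.0,
    seed: int | None = None,
) -> SeizureEpisode:
    """Simulate a focal seizure recorded at a distance.

    Timeline: interictal spikes (IIS) occur at the focus with a rate ramping
    from ``iis_rate_early`` to ``iis_rate_late`` over the pre-ictal window; the
    k-th IIS couples into the imaged field with strength min(1, k * ramp), so
    early events leave the imaged cells untouched while late ones depolarise
    them with growing amplitude.  At ``preictal_window`` the electrographic
    seizure starts at the focus: imaged cells depolarise almost synchronously
    (fast subthreshold pathway, jitter ``ictal_sync_jitter``) while spiking
    recruitment arrives at distance/wavefront_speed from the focus.
    """
    if duration <= sz.preictal_window + 1.0:
        raise ValueError("duration must cover preictal_window plus an ictal period")
    rng = np.random.default_rng(seed)
    n = int(round(duration * VM_RATE))
    t = np.arange(n) / VM_RATE
    n_cells = scene.n_cells
    t_onset = sz.preictal_window

    # --- focus interictal spikes (rate ramps early -> late), by thinning
    cand = _poisson_times(sz.iis_rate_late, t_onset - 1.0, rng) + 0.5
    keep = rng.uniform(size=cand.size) < (
        sz.iis_rate_early + (sz.iis_rate_late - sz.iis_rate_early) * cand / t_onset
    ) / sz.iis_rate_late
    iis_times = cand[keep]
    coupling = np.minimum(1.0, np.arange(iis_times.size) * sz.iis_coupling_ramp)

    # --- focus trace: sharp IIS deflections + tonic ictal depolarisation
    focus_vm = np.full(n, dyn.v_rest, dtype=np.float64)
    for o in iis_times:
        _add_kernel(focus_vm, o, _event_kernel(25.0, 0.08))
    plateau = _plateau_kernel(duration - t_onset, 25.0)
    _add_kernel(focus_vm, t_onset, plateau)
    osc = 20.0 * np.sin(2 * np.pi * 4.0 * (t - t_onset))
    focus_vm += np.where(t >= t_onset, osc * (1 - np.exp(-(t - t_onset) / 0.5)), 0.0)
    # ongoing background synaptic bombardment: a noise-free LFP would make any
    # threshold on its baseline meaningless
    bg = ndimage.gaussian_filter1d(rng.standard_normal(n), 20.0)
    focus_vm += 1.5 * bg / bg.std()

    # --- imaged cells
    vm = np.full((n_cells, n), dyn.v_rest, dtype=np.float64)
    spikes: list[list[float]] = [[] for _ in range(n_cells)]
    events: list[dict] = []
    x = scene.cell_positions[:, 0]
    fast_delay = (sz.focus_offset + x) / SUBTHRESHOLD_SPEED
    span = dyn.spike_threshold - dyn.v_rest

    # an IIS reaches the imaged field only when its synaptic barrage escapes
    # surround inhibition: gate probability and coupled amplitude both ramp
    # toward onset, so early events leave no optical trace while late ones
    # arrive as population EPSPs
    iis_decay = 0.25
    for k, (o, c_k) in enumerate(zip(iis_times, coupling)):
        if c_k <= 0 or rng.uniform() >= c_k:
            continue
        for c in range(n_cells):
            amp = c_k * sz.iis_amp * (1.0 + 0.1 * rng.standard_normal())
            if amp <= 0.2:
                continue
            onset = o + fast_delay[c]
            _add_kernel(vm[c], onset, _event_kernel(amp, iis_decay))
            events.append(dict(roi=f"cell_{c:03d}", onset=onset,
                               peak_time=onset + event_kernel_peak_delay(iis_decay),
                               amplitude_mv=amp, kind="iis", spiking=False))

    sub_onsets = t_onset + fast_delay + np.abs(rng.standard_normal(n_cells)) * sz.ictal_sync_jitter
    rec_times = t_onset + (sz.focus_offset + x) / sz.wavefront_speed
    ictal_plateau_amp = min(sz.ictal_amp, 0.9 * span)
    for c in range(n_cells):
        _add_kernel(vm[c], sub_onsets[c], _plateau_kernel(duration - sub_onsets[c],
                                                          ictal_plateau_amp))
        events.append(dict(roi=f"cell_{c:03d}", onset=sub_onsets[c],
                           peak_time=sub_onsets[c] + 0.15,
                           amplitude_mv=ictal_plateau_amp, kind="ictal-sub",
                           spiking=False))
        if rec_times[c] < duration - 0.5:
            # recruitment: suprathreshold burst, then sustained ictal firing
            _add_kernel(vm[c], rec_times[c], _event_kernel(span * 0.5 + 5.0, 0.3))
            for k in range(5):
                ts = rec_times[c] + 0.04 * k
                if ts < duration:
                    spikes[c].append(ts)
            for ts in rec_times[c] + 0.3 + _poisson_times(3.0, duration - rec_times[c] - 0.3, rng):
                spikes[c].append(float(ts))
            events.append(dict(roi=f"cell_{c:03d}", onset=rec_times[c],
                               peak_time=rec_times[c] + event_kernel_peak_delay(0.3),
                               amplitude_mv=span * 0.5 + 5.0, kind="ictal-spike",
                               spiking=True))

    # low-level background EPSPs
    for c in range(n_cells):
        for o in _poisson_times(dyn.epsp_rate, duration, rng):
            amp = max(dyn.epsp_amp * (1.0 + 0.2 * rng.standard_normal()), 0.1)
            _add_kernel(vm[c], o, _event_kernel(amp, 0.05))

    spike_arr = [_strictly_increasing(np.array(sorted(s))) for s in spikes]
    events.sort(key=lambda e: (e["roi"], e["onset"]))
    pop = VoltagePopulation(t=t, vm=vm, spike_times=spike_arr, events=events)
    gt = GroundTruth(spike_times=spike_arr, events=events, vm=vm,
                     lfp_onset=t_onset, recruitment_times=rec_times,
                     subthreshold_onsets=sub_onsets)
    return SeizureEpisode(population=pop, focus_vm=focus_vm[None, :],
                          iis_times=iis_times, iis_coupling=coupling,
                          ground_truth=gt)


def _plateau_kernel(length: float, amp: float, rate: float = VM_RATE) -> np.ndarray:
    """Sustained depolarisation: fast sigmoid-like rise, very slow decay."""
    t = np.arange(0.0, max(length, 0.1), 1.0 / rate)
    return amp * (1.0 - np.exp(-t / 0.1)) * np.exp(-t / 60.0)


# ---------------------------------------------------------------------------
# indicator forward models
# ---------------------------------------------------------------------------

def _one_pole(x: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """Exact first-order low-pass: for a step input the output relaxes as
    1 - exp(-t/tau) with no discretisation bias."""
    if tau <= 0:
        return x.copy()
    a = 1.0 - math.exp(-dt / tau)
    b = np.array([a])
    aa = np.array([1.0, -(1.0 - a)])
    zi = np.array([(1.0 - a) * x[0]])
    y, _ = signal.lfilter(b, aa, x, zi=zi)
    return y


def sensor_fluorescence(vm: np.ndarray, m: SensorModel, rate: float = VM_RATE) -> np.ndarray:
    """Fluorescence (arbitrary units) emitted by a voltage sensor.

    The steady-state Boltzmann response to ``vm`` is low-pass filtered by the
    two-exponential kinetics (weights ``frac_fast``/``1 - frac_fast``) and
    multiplied by the photobleaching decay exp(-t/tau_bleach).
    """
    vm = np.asarray(vm, dtype=np.float64)
    if not np.all(np.isfinite(vm)):
        raise ValueError("vm contains non-finite values")
    if m.targeting == "null":
        base = np.ones_like(vm)
    else:
        ss = m.steady_state(vm)
        dt = 1.0 / rate
        base = (m.frac_fast * _one_pole(ss, m.tau_fast, dt)
                + (1.0 - m.frac_fast) * _one_pole(ss, m.tau_slow, dt))
    t = np.arange(vm.size) / rate
    if m.tau_bleach > 0 and math.isfinite(m.tau_bleach):
        base = base * np.exp(-t / m.tau_bleach)
    return base


def calcium_fluorescence(
    spikes, vm: np.ndarray | None, c: CalciumModel, rate: float = VM_RATE
) -> np.ndarray:
    """Calcium-channel fluorescence: baseline 1 plus one double-exponential
    transient of amplitude ``a_spike`` per spike (linear in spike count)."""
    if vm is None:
        raise ValueError("vm trace required to define the time base")
    vm = np.asarray(vm, dtype=np.float64)
    n = vm.size
    duration = n / rate
    spikes = np.atleast_1d(np.asarray(spikes, dtype=float)) if np.size(spikes) else np.empty(0)
    if spikes.size and (spikes.min() < 0 or spikes.max() > duration):
        raise ValueError("spike times must lie within the trace duration")
    f = np.ones(n, dtype=np.float64)
    if spikes.size:
        t_max = 8.0 * c.tau_decay
        tk = np.arange(0.0, t_max, 1.0 / rate)
        k = np.exp(-tk / c.tau_decay) - np.exp(-tk / c.tau_rise)
        k = c.a_spike * k / k.max()
        for s in spikes:
            _add_kernel(f, s, k, rate)
    if c.subthreshold_gain != 0.0:
        f = f + c.subthreshold_gain * (vm - np.median(vm))
    return f


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _bin_to_frames(traces: np.ndarray, rate: float, frame_rate: float) -> np.ndarray:
    """Box-average 1 kHz traces into imaging frames (frame k averages samples
    in [k/frame_rate, (k+1)/frame_rate))."""
    n = traces.shape[-1]
    n_frames = int(math.floor(n / rate * frame_rate))
    edges = np.floor(np.arange(n_frames + 1) * rate / frame_rate).astype(int)
    sums = np.add.reduceat(traces, edges[:-1], axis=-1)
    counts = np.diff(edges)
    return sums / counts


def render_dual_channel_movie(
    volt_traces: np.ndarray,
    ca_traces: np.ndarray,
    scene: ScenePlan,
    noise: NoiseModel,
    frame_rate: float = 30.0,
    rate: float = VM_RATE,
    seed: int | None = None,
) -> tuple[FrameStack, FrameStack, np.ndarray]:
    """Render per-cell fluorescence traces into two seeded movies.

    Per-pixel intensity is the soma/neuropil weight times the trace value
    integrated to the frame rate; the heartbeat multiplies whole frames; motion
    applies a rigid per-frame shift; shot noise is Poisson (mean-preserving in
    expectation); flash frames saturate at full scale.  Returns the voltage
    stack, the calcium stack, and the true per-frame (row, col) motion.
    """
    volt_traces = np.atleast_2d(np.asarray(volt_traces, dtype=np.float64))
    ca_traces = np.atleast_2d(np.asarray(ca_traces, dtype=np.float64))
    if volt_traces.shape != ca_traces.shape:
        raise ValueError("voltage and calcium traces must share a time base")
    if volt_traces.shape[0] != scene.n_cells:
        raise ValueError("one trace per scene cell required")
    rng = np.random.default_rng(seed)
    H, W = scene.shape
    v_frames = _bin_to_frames(volt_traces, rate, frame_rate)
    c_frames = _bin_to_frames(ca_traces, rate, frame_rate)
    n_frames = v_frames.shape[1]
    for i in noise.flash_frames:
        if not (0 <= i < n_frames):
            raise ValueError(f"flash frame {i} outside stack of {n_frames} frames")

    masks = scene.cell_masks()
    soma_any = np.any(masks, axis=0)
    npil = ~soma_any
    t_frames = (np.arange(n_frames) + 0.5) / frame_rate
    heart = 1.0 + noise.heartbeat_amp * np.sin(2 * np.pi * noise.heartbeat_freq * t_frames)
    motion = (rng.standard_normal((n_frames, 2)) * noise.motion_sd
              if noise.motion_sd > 0 else np.zeros((n_frames, 2)))

    stacks = []
    for frames, chan in ((v_frames, "voltage"), (c_frames, "calcium")):
        npil_trace = scene.neuropil_level * frames.mean(axis=0)
        movie = np.empty((n_frames, H, W), dtype=np.float64)
        base = np.full((H, W), 0.05)
        for k in range(n_frames):
            img = base.copy()
            img[npil] += npil_trace[k]
            for m, y in zip(masks, frames[:, k]):
                img[m] = y
            if noise.psf_sigma > 0:
                img = ndimage.gaussian_filter(img, noise.psf_sigma)
            img *= heart[k]
            if motion[k, 0] != 0 or motion[k, 1] != 0:
                img = ndimage.shift(img, motion[k], order=1, mode="constant",
                                    cval=float(np.median(img)))
            movie[k] = img
        if noise.photon_scale > 0:
            counts = rng.poisson(np.clip(movie, 0, None) * noise.photon_scale).astype(np.float64)
        else:
            counts = np.round(movie * DIGITAL_GAIN)
        counts = np.clip(counts, 0, FULL_SCALE)
        for i in noise.flash_frames:
            counts[i] = FULL_SCALE
        stacks.append(FrameStack(counts.astype(np.uint16), frame_rate, channel=chan,
                                 origin="synthetic"))
    return stacks[0], stacks[1], motion


def synthesize_lfp(vm: np.ndarray, rate: float = VM_RATE, scale: float = 1.0) -> Trace:
    """Surrogate LFP: negated, scaled population-mean deviation of membrane
    potential from rest (synchronous depolarisation gives a negative
    deflection), on the voltage time base."""
    vm = np.atleast_2d(np.asarray(vm, dtype=np.float64))
    if vm.shape[0] < 1 or vm.size == 0:
        raise ValueError("at least one voltage trace required")
    rest = np.median(vm, axis=1, keepdims=True)
    lfp = -scale * (vm - rest).mean(axis=0)
    t = np.arange(vm.shape[1]) / rate
    return Trace(t, lfp, kind="electrical", label="lfp")
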