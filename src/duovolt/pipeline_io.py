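"""File I/O, scenario configuration, and one-command scenario execution
(simulate -> preprocess -> traces -> events -> network -> summary)."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import calibration, events as ev, network, synthgen, traces as tr
from .preprocess import FrameStack, KalmanParams, kalman_stack_filter, register_rigid, \
    replace_stimulus_frames
from .traces import ROISet, Trace, TraceSet

log = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "StageError",
    "load_stack",
    "write_stack",
    "write_lfp",
    "load_lfp",
    "write_tables",
    "write_ground_truth",
    "default_config",
    "config_hash",
    "load_config",
    "save_config",
    "run_scenario",
]


class ConfigError(ValueError):
    """Invalid scenario configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""


# ---------------------------------------------------------------------------
# stacks, LFP, tables
# ---------------------------------------------------------------------------

def write_stack(stack: FrameStack, path) -> Path:
    """Write a multi-page 16-bit grayscale TIFF plus a JSON sidecar carrying
    the frame rate and channel."""
    path = Path(path)
    data = stack.data
    if data.dtype != np.uint16:
        data = np.clip(np.round(data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(
        dict(frame_rate=stack.frame_rate, channel=stack.channel, origin=stack.origin)))
    return path


def load_stack(path, frame_rate: float | None = None, channel: str | None = None) -> FrameStack:
    """Load a multi-page grayscale stack.

    The frame rate comes from the sidecar JSON written by :func:`write_stack`,
    or from the ``frame_rate`` argument; RGB or ragged stacks are rejected.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected a T x H x W grayscale stack, got shape {data.shape}")
    if data.dtype.kind not in "ui" or data.dtype.itemsize > 2:
        raise ValueError("expected 8/16-bit grayscale data")
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    rate = frame_rate if frame_rate is not None else meta.get("frame_rate")
    if rate is None:
        raise ValueError("frame rate metadata missing; pass frame_rate (--rate)")
    return FrameStack(data, float(rate), channel=channel or meta.get("channel", "voltage"),
                      origin=str(path))


def write_lfp(lfp: Trace, path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": lfp.t, "lfp": lfp.y}).to_csv(path, index=False)
    return path


def load_lfp(path) -> Trace:
    df = pd.read_csv(path)
    return Trace(df["time_s"].to_numpy(), df["lfp"].to_numpy(), kind="electrical",
                 label="lfp")


def traceset_frame(ts: TraceSet) -> pd.DataFrame:
    rows = []
    for t in ts:
        rows.append(pd.DataFrame({"roi": t.label, "t": t.t, "y": t.y, "kind": t.kind}))
    return pd.concat(rows, ignore_index=True) if rows else \
        pd.DataFrame(columns=["roi", "t", "y", "kind"])


def write_tables(outdir, event_tables: dict | None = None, tracesets: dict | None = None,
                 fits: dict | None = None) -> list[Path]:
    """Write event tables / tracesets as CSV and fits as JSON, with
    deterministic column order and row sort.  Empty tables produce
    header-only files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in (event_tables or {}).items():
        p = outdir / f"{name}.csv"
        df = table.to_frame().sort_values(["roi", "onset_s"], kind="mergesort")
        df.to_csv(p, index=False)
        written.append(p)
    for name, ts in (tracesets or {}).items():
        p = outdir / f"{name}.csv"
        traceset_frame(ts).to_csv(p, index=False)
        written.append(p)
    for name, fit in (fits or {}).items():
        p = outdir / f"{name}.json"
        p.write_text(json.dumps(fit, indent=2, sort_keys=True, default=_jsonable))
        written.append(p)
    return written


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer, np.bool_)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serialisable: {type(x)}")


def write_ground_truth(gt: synthgen.GroundTruth, outdir) -> tuple[Path, Path]:
    """Ground truth as JSON (markers, spikes, motion) + CSV event table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = dict(
        spike_times=[s.tolist() for s in gt.spike_times],
        lfp_onset=gt.lfp_onset,
        recruitment_times=None if gt.recruitment_times is None else gt.recruitment_times.tolist(),
        subthreshold_onsets=None if gt.subthreshold_onsets is None else gt.subthreshold_onsets.tolist(),
        motion=None if gt.motion is None else gt.motion.tolist(),
    )
    jpath = outdir / "ground_truth.json"
    jpath.write_text(json.dumps(payload, indent=2))
    cpath = outdir / "ground_truth_events.csv"
    pd.DataFrame(gt.events).to_csv(cpath, index=False)
    return jpath, cpath


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def default_config(scenario: str = "physiological", seed: int = 0,
                   outdir: str | None = None) -> dict:
    """Built-in scenario configurations (all parameters overridable)."""
    if scenario not in ("physiological", "seizure", "calibration"):
        raise ConfigError(f"unknown scenario {scenario!r}")
    cfg = {
        "scenario": scenario,
        "seed": int(seed),
        "outdir": outdir,
        "duration": 180.0 if scenario == "physiological" else 60.0,
        "frame_rate": 30.0,
        "scene": {"n_cells": 20, "fov": [128.0, 128.0], "pixel_size": 2.0,
                  "soma_radius": 6.0, "neuropil_level": 0.3},
        "dynamics": {},
        "sensor": {"variant": "st"},
        "calcium": {},
        # two-photon cellular regime: heartbeat far weaker than in wide-field,
        # shot noise set so detected event SNR lands near 6
        "noise": {"heartbeat_freq": 7.0, "heartbeat_amp": 0.003, "photon_scale": 1200.0,
                  "motion_sd": 0.25, "flash_frames": []},
        "stim": {"start": 10.0, "period": 12.0},
        "preprocess": {"register": True, "kalman_gain": 0.80, "kalman_noise_var": 0.05},
        "analysis": {"knot_spacing": 20.0, "threshold_sd": 3.0, "min_dur": 0.1,
                     "coincidence": 0.2, "match_tol": 0.5, "min_gt_amp": 20.0},
        "seizure": {},
    }
    if scenario == "seizure":
        cfg["stim"] = None
        cfg["duration"] = 60.0
        cfg["analysis"]["interictal_sd"] = 5.0
        cfg["analysis"]["onset_sustain"] = 2.0
        cfg["analysis"]["interictal_width"] = 2
        cfg["seizure"] = {"preictal_window": 40.0, "focus_offset": 500.0,
                          "wavefront_speed": 100.0, "iis_rate_early": 0.4,
                          "iis_rate_late": 1.0, "iis_coupling_ramp": 0.03,
                          "ictal_sync_jitter": 0.05}
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=_jsonable).encode()
    ).hexdigest()[:16]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "scenario" not in cfg:
        raise ConfigError("config must be a mapping with a 'scenario' key")
    base = default_config(cfg["scenario"], seed=cfg.get("seed", 0))
    _deep_update(base, cfg)
    return base


def save_config(cfg: dict, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return path


def _deep_update(base: dict, upd: dict) -> dict:
    for k, v in upd.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


# ---------------------------------------------------------------------------
# ground-truth matching
# ---------------------------------------------------------------------------

def match_classification(gt_events: list[dict], labeled: ev.EventTable,
                         tol: float = 0.3, min_amp: float = 10.0) -> dict:
    """Compare detected spiking/subthreshold labels against ground truth.

    Only ground-truth events large enough to be detectable (``min_amp`` mV)
    are scored; an undetected ground-truth event counts as a disagreement.
    Returns a confusion-matrix dict and the overall label agreement.
    """
    det = [e for e in labeled.events if e.label in ("spiking", "subthreshold")]
    gt = [g for g in gt_events if g["amplitude_mv"] >= min_amp]
    confusion = {"spiking": {"spiking": 0, "subthreshold": 0, "missed": 0},
                 "subthreshold": {"spiking": 0, "subthreshold": 0, "missed": 0}}
    used: set[int] = set()
    for g in gt:
        true_label = "spiking" if g["spiking"] else "subthreshold"
        best, best_dt = None, tol
        for i, e in enumerate(det):
            if i in used or e.roi != g["roi"]:
                continue
            dt = abs(e.onset - g["onset"])
            if dt <= best_dt:
                best, best_dt = i, dt
        if best is None:
            confusion[true_label]["missed"] += 1
        else:
            used.add(best)
            confusion[true_label][det[best].label] += 1
    n_gt = len(gt)
    n_correct = confusion["spiking"]["spiking"] + confusion["subthreshold"]["subthreshold"]
    extras = len(det) - len(used)
    return dict(confusion=confusion, n_ground_truth=n_gt, n_detected=len(det),
                n_unmatched_detections=extras,
                agreement=n_correct / n_gt if n_gt else None)


# ---------------------------------------------------------------------------
# scenario execution
# ---------------------------------------------------------------------------

def _scene_rois(scene: synthgen.ScenePlan) -> ROISet:
    masks = scene.cell_masks()
    labels = [f"cell_{i:03d}" for i in range(scene.n_cells)]
    return ROISet(masks, labels, scene.cell_positions.copy(), kind="soma")


def _preprocess_pair(stack_v: FrameStack, stack_c: FrameStack,
                     cfg: dict) -> tuple[FrameStack, FrameStack]:
    """Deflash, register (shifts estimated on the voltage channel and applied
    to both, since the channels are acquired simultaneously), Kalman filter."""
    from .preprocess import apply_shifts

    pp = cfg["preprocess"]
    flash = cfg["noise"].get("flash_frames") or []
    if flash:
        stack_v = replace_stimulus_frames(stack_v, flash)
        stack_c = replace_stimulus_frames(stack_c, flash)
    if pp.get("register", True):
        stack_v, shifts = register_rigid(stack_v)
        stack_c = apply_shifts(stack_c, shifts)
    params = KalmanParams(pp["kalman_gain"], pp["kalman_noise_var"])
    return kalman_stack_filter(stack_v, params), kalman_stack_filter(stack_c, params)


def _extract_dff(stack: FrameStack, rois: ROISet, knot_spacing: float) -> TraceSet:
    raw = tr.extract_traces(stack, rois)
    return TraceSet([tr.compute_dff_spontaneous(x, knot_spacing) for x in raw])


def _simulate_common(cfg: dict):
    ss = np.random.SeedSequence(cfg["seed"])
    sim_seed, render_seed, scene_seed = [int(s.generate_state(1)[0]) for s in ss.spawn(3)]
    scene = synthgen.default_scene(seed=scene_seed, **{
        k: (tuple(v) if k == "fov" else v) for k, v in cfg["scene"].items()})
    dyn = synthgen.VoltageDynamics(**cfg["dynamics"])
    sensor = synthgen.default_sensor(cfg["sensor"].get("variant", "st"))
    cal = synthgen.CalciumModel(**cfg["calcium"])
    noise = synthgen.NoiseModel(**{**cfg["noise"],
                                   "flash_frames": tuple(cfg["noise"].get("flash_frames") or [])})
    return scene, dyn, sensor, cal, noise, sim_seed, render_seed


def run_scenario(cfg: dict, outdir=None) -> dict:
    """Execute a full scenario and return (and optionally write) the summary.

    Stages: simulate -> render -> preprocess -> traces -> events -> network.
    Any stage failure raises :class:`StageError` tagged with the stage name.
    """
    scenario = cfg.get("scenario")
    if scenario not in ("physiological", "seizure", "calibration"):
        raise ConfigError(f"unknown scenario {scenario!r}")
    outdir = Path(outdir or cfg.get("outdir") or ".") if (outdir or cfg.get("outdir")) else None
    try:
        if scenario == "physiological":
            summary = _run_physiological(cfg, outdir)
        elif scenario == "seizure":
            summary = _run_seizure(cfg, outdir)
        else:
            summary = _run_calibration(cfg)
    except (ConfigError, StageError):
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(f"scenario {scenario} failed: {exc}") from exc
    summary["config_hash"] = config_hash(cfg)
    summary["scenario"] = scenario
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=_jsonable))
        save_config(cfg, outdir / "config.yaml")
    return summary


def _forward_and_render(pop, scene, sensor, cal, noise, cfg, render_seed):
    volt_f = np.stack([synthgen.sensor_fluorescence(v, sensor) for v in pop.vm])
    ca_f = np.stack([synthgen.calcium_fluorescence(s, v, cal)
                     for s, v in zip(pop.spike_times, pop.vm)])
    stack_v, stack_c, motion = synthgen.render_dual_channel_movie(
        volt_f, ca_f, scene, noise, frame_rate=cfg["frame_rate"], seed=render_seed)
    return stack_v, stack_c, motion


def _run_physiological(cfg: dict, outdir) -> dict:
    a = cfg["analysis"]
    scene, dyn, sensor, cal, noise, sim_seed, render_seed = _simulate_common(cfg)
    stim = cfg.get("stim")
    stim_times = (np.arange(stim["start"], cfg["duration"] - 2.0, stim["period"])
                  if stim else np.empty(0))
    log.info("stage=simulate scenario=physiological seed=%s", cfg["seed"])
    pop = synthgen.simulate_population_voltage(dyn, scene, stim_times, cfg["duration"],
                                               seed=sim_seed)
    stack_v, stack_c, motion = _forward_and_render(pop, scene, sensor, cal, noise, cfg,
                                                   render_seed)
    gt = synthgen.GroundTruth(spike_times=pop.spike_times, events=pop.events,
                              vm=pop.vm, motion=motion)
    log.info("stage=preprocess frames=%d", stack_v.n_frames)
    stack_v, stack_c = _preprocess_pair(stack_v, stack_c, cfg)
    rois = _scene_rois(scene)
    dff_v = _extract_dff(stack_v, rois, a["knot_spacing"])
    dff_c = _extract_dff(stack_c, rois, a["knot_spacing"])

    log.info("stage=events rois=%d", len(rois))
    labeled_all = []
    for lab in rois.labels:
        tv = ev.detect_voltage_events(dff_v[lab], a["threshold_sd"], a["min_dur"])
        tc = ev.detect_calcium_transients(dff_c[lab], a["threshold_sd"], a["min_dur"])
        labeled_all.extend(ev.classify_events(tv, tc, a["coincidence"]).events)
    labeled = ev.EventTable(labeled_all, config=dict(a))
    score = match_classification(gt.events, labeled, tol=a["match_tol"],
                                 min_amp=a["min_gt_amp"])

    corr = network.correlation_matrix(dff_v)
    label_counts = {}
    for e in labeled.events:
        label_counts[e.label] = label_counts.get(e.label, 0) + 1
    summary = dict(
        n_cells=scene.n_cells,
        n_events_detected=len(labeled),
        event_label_counts=label_counts,
        classification=score,
        mean_pairwise_r=float(np.nanmean(corr.r[np.triu_indices(len(corr.labels), 1)])),
        stim_times=stim_times.tolist(),
    )
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        write_stack(stack_v, outdir / "movie_volt.tif")
        write_stack(stack_c, outdir / "movie_ca.tif")
        write_lfp(synthgen.synthesize_lfp(pop.vm), outdir / "lfp.csv")
        write_ground_truth(gt, outdir)
        write_tables(outdir, event_tables={"events": labeled},
                     tracesets={"traces_volt": dff_v, "traces_ca": dff_c})
    return summary


def _run_seizure(cfg: dict, outdir) -> dict:
    a = cfg["analysis"]
    scene, dyn, sensor, cal, noise, sim_seed, render_seed = _simulate_common(cfg)
    sz = synthgen.SeizureConfig(**cfg["seizure"])
    log.info("stage=simulate scenario=seizure seed=%s", cfg["seed"])
    ep = synthgen.simulate_seizure_episode(dyn, scene, sz, cfg["duration"], seed=sim_seed)
    pop = ep.population
    stack_v, stack_c, motion = _forward_and_render(pop, scene, sensor, cal, noise, cfg,
                                                   render_seed)
    ep.ground_truth.motion = motion
    lfp = synthgen.synthesize_lfp(ep.focus_vm)
    lfp_bp = network.bandpass_lfp(lfp)

    log.info("stage=preprocess frames=%d", stack_v.n_frames)
    stack_v, stack_c = _preprocess_pair(stack_v, stack_c, cfg)
    rois = _scene_rois(scene)
    dff_v = _extract_dff(stack_v, rois, a["knot_spacing"])
    dff_c = _extract_dff(stack_c, rois, a["knot_spacing"])
    # optical field potential: whole-FOV mean of the voltage channel
    grid = tr.partition_fov(stack_v.data.shape[1:], 1, 1, scene.pixel_size)
    ofp = tr.compute_dff_spontaneous(
        tr.extract_traces(stack_v, grid)[tr.FULL_FOV_LABEL], a["knot_spacing"])

    log.info("stage=network onset analysis")
    baseline_w = (0.0, min(10.0, 0.25 * cfg["duration"]))
    markers = network.seizure_onsets(lfp_bp, {"voltage": dff_v, "calcium": dff_c},
                                     sustain={"lfp": a.get("onset_sustain", 2.0),
                                              "voltage": a.get("onset_sustain", 2.0),
                                              "calcium": 0.5},
                                     baseline_window=baseline_w,
                                     threshold_sd=a["threshold_sd"],
                                     min_fraction=a.get("onset_min_fraction", 0.25))
    v_delays = [d for k, d in markers.delays.items()
                if k.startswith("voltage:") and d is not None]
    c_delays = [d for k, d in markers.delays.items()
                if k.startswith("calcium:") and d is not None]
    onset = markers.lfp_onset if markers.lfp_onset is not None else sz.preictal_window
    win_corr = network.windowed_lfp_optical_correlation(lfp_bp, ofp, onset=onset)

    # interictal counts in the early window (surround inhibition regime)
    early = (1.0, min(13.0, sz.preictal_window / 3.0))
    def _crop(trace: Trace, lo, hi):
        sel = (trace.t >= lo) & (trace.t < hi)
        return Trace(trace.t[sel], trace.y[sel], trace.kind, trace.label)
    ii_sd = a.get("interictal_sd", a["threshold_sd"])
    ii_w = a.get("interictal_width", 1)
    _, lfp_rate_early = ev.detect_interictal_events(_crop(lfp_bp, *early), ii_sd)
    opt_counts = 0
    for ts in (dff_v, dff_c):
        for trc in ts:
            table, _ = ev.detect_interictal_events(_crop(trc, *early), ii_sd,
                                                   min_width=ii_w)
            opt_counts += len(table)
    lfp_count_early = int(round(lfp_rate_early * (early[1] - early[0])))

    recruit = None
    if len(markers.recruitment_times) >= 3:
        positions = dict(zip(rois.labels, scene.cell_positions))
        recruit = network.recruitment_order(markers.recruitment_times, positions)

    # interictal EPSP amplitudes per cell (voltage channel, depolarising)
    pre_list = []
    for trc in dff_v:
        t_pre, _ = ev.detect_interictal_events(_crop(trc, 0.0, onset),
                                               a["threshold_sd"], direction=-1)
        pre_list.extend(t_pre.events)
    pre_events = ev.EventTable(pre_list)
    pre_stats = ev.preictal_window_stats(pre_events, onset)

    summary = dict(
        lfp_onset=markers.lfp_onset,
        true_lfp_onset=ep.ground_truth.lfp_onset,
        median_voltage_delay=float(np.median(v_delays)) if v_delays else None,
        median_calcium_delay=float(np.median(c_delays)) if c_delays else None,
        n_voltage_onsets=len(v_delays),
        n_calcium_onsets=len(c_delays),
        windowed_correlation=win_corr,
        early_interictal=dict(lfp_count=lfp_count_early, optical_count=opt_counts,
                              window=early),
        recruitment=None if recruit is None else
            dict(speed=recruit["speed"], synchronous=recruit["synchronous"],
                 r_squared=recruit["r_squared"], order=recruit["order"]),
        true_wavefront_speed=sz.wavefront_speed,
        preictal_amplitude_windows=pre_stats,
        n_iis=int(ep.iis_times.size),
    )
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        write_stack(stack_v, outdir / "movie_volt.tif")
        write_stack(stack_c, outdir / "movie_ca.tif")
        write_lfp(lfp, outdir / "lfp.csv")
        write_ground_truth(ep.ground_truth, outdir)
        write_tables(outdir, tracesets={"traces_volt": dff_v, "traces_ca": dff_c,
                                        "ofp": TraceSet([ofp])})
    return summary


def _run_calibration(cfg: dict) -> dict:
    """Characterise the configured sensor: F-V fit, kinetics fit, bleach fit."""
    sensor = synthgen.default_sensor(cfg["sensor"].get("variant", "st"))
    v = np.linspace(-120.0, 60.0, 19)
    f = sensor.steady_state(v)
    dff = f / f[0] - 1.0
    fv = calibration.fit_fv_curve(v, dff)

    rate = synthgen.VM_RATE
    n = int(2.0 * rate)
    vm = np.full(n, -70.0)
    vm[int(0.2 * rate):] = -50.0
    fstep = synthgen.sensor_fluorescence(
        vm, synthgen.SensorModel(tau_bleach=np.inf, v_half=sensor.v_half,
                                 k_slope=sensor.k_slope, df_max=sensor.df_max,
                                 polarity=sensor.polarity, tau_fast=sensor.tau_fast,
                                 tau_slow=sensor.tau_slow, frac_fast=sensor.frac_fast))
    i0 = int(0.2 * rate)
    kin = calibration.fit_double_exponential(np.arange(n - i0) / rate, fstep[i0:])

    t = np.arange(0, 60.0, 1.0 / 30.0)
    bleach = np.exp(-t / sensor.tau_bleach) if np.isfinite(sensor.tau_bleach) else None
    tau_b, scale_b = (calibration.fit_single_exponential(t, bleach)
                      if bleach is not None else (None, None))
    return dict(
        fv=dict(v_half=fv.v_half, k_slope=fv.k_slope, amplitude=fv.amplitude,
                baseline=fv.baseline, slope_at_rest=fv.slope_at(-68.5)),
        kinetics=dict(tau_fast_ms=kin.tau1 * 1e3, tau_slow_ms=kin.tau2 * 1e3,
                      a1=kin.a1, a2=kin.a2, rss=kin.rss),
        bleach=dict(tau_s=tau_b, scale=scale_b),
        sensor=dict(variant=cfg["sensor"].get("variant", "st")),
    )
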