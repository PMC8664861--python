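# duovolt

Simulation and analysis of simultaneous two-photon **voltage** and **calcium**
imaging movies — from raw dual-channel image stacks to discriminated
subthreshold/spiking events and seizure-propagation statistics.

The package has two halves that check each other:

* **`duovolt.synthgen`** — a seeded generator of dual-channel movies. It
  simulates layer-2/3 membrane-potential dynamics (UP states, EPSPs, visually
  evoked potentials, spikes) at 1 kHz, passes them through indicator forward
  models (a Boltzmann fluorescence–voltage sensor with two-exponential
  kinetics and photobleaching; a spike-number-linear calcium indicator),
  and renders 30 Hz 16-bit movies with heartbeat gain artifact, shot noise,
  motion jitter and stimulus flash frames, plus a surrogate LFP and complete
  ground truth. A focal-seizure scenario adds pre-ictal interictal barrages
  with escalating coupling and a slowly propagating ictal wavefront.
* **the analysis pipeline** — `preprocess` (flash-frame replacement, rigid
  registration, per-pixel temporal Kalman filter), `traces` (ROI/grid/FOV
  extraction, spline detrending, ΔF/F, SNR, stimulus-triggered averages),
  `calibration` (Boltzmann F–V fits, single/double exponential kinetics,
  detection-limit algebra, R²), `events` (threshold event detection and
  spiking/subthreshold/calcium-only classification), and `network`
  (LFP band-pass, correlation structure, correlation vs. distance, windowed
  LFP–optical cross-correlation, seizure onset delays, recruitment order,
  propagation-pattern labels).

`duovolt.pipeline_io` ties everything together: scenario configs (YAML),
stack/trace/event I/O, and `run_scenario` which executes
simulate → preprocess → traces → events → network and writes a summary JSON
(including a classification confusion matrix against ground truth).

## Test

```bash
python -m pytest tests/
```

The suite includes `tests/test_acceptance.py`, which re-derives the headline
quantities (heartbeat peak rate, fast kinetic component, detection limit,
filter-oracle equivalence, parameter recovery, classification agreement, and
the seizure ordering properties) from seeded simulations. The full run takes
roughly five minutes on one CPU; most of that is the ten-seed scenario
batteries in the acceptance module.

## Command line

```bash
# generate + analyse a complete scenario in one step
duovolt run --scenario physiological --seed 1 --out out/phys
duovolt run --scenario seizure --seed 1 --out out/sz

# individual stages
duovolt simulate --scenario seizure --seed 2 --out out/sim
duovolt preprocess --volt movie_volt.tif --ca movie_ca.tif --out out/pp
duovolt traces --stack out/pp/corrected_volt.tif --grid 4x4 --out traces.csv
duovolt events --volt traces_v.csv --ca traces_c.csv --out events.csv
duovolt calibrate limit --in baseline.csv --slope -0.1908 --out fit.json
duovolt network lfpfilter --lfp lfp.csv --out lfp_bp.csv
```

Exit codes: 0 ok, 2 configuration error, 3 stage failure.

Scenario outputs are two multi-page 16-bit TIFF stacks (`movie_volt.tif`,
`movie_ca.tif`, each with a JSON sidecar carrying the frame rate), the LFP as
a two-column CSV, ground truth as JSON + CSV, long-format trace CSVs, an event
table CSV, and `summary.json` stamped with the config hash.

## Conventions

Times are seconds, positions micrometres, frame indices 0-based; frame *k*
spans `[k/rate, (k+1)/rate)`. ΔF/F is stored as a dimensionless fraction and
rendered as percent only in reports. Voltage-channel deflections are
negative-going (fluorescence decreases on depolarisation); calcium transients
are positive-going. Every operation is a pure function of its inputs and an
explicit seed.
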