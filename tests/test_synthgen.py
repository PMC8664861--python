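import math

import numpy as np
import pytest

from duovolt import synthgen as sg
from duovolt.traces import partition_fov, extract_traces, FULL_FOV_LABEL


def boltzmann_oracle(v, m):
    """Direct evaluation of the sensor's steady-state curve, written out
    independently of SensorModel.steady_state."""
    sig = 1.0 / (1.0 + math.exp(-(v - m.v_half) / m.k_slope))
    return 1.0 + m.df_max * m.polarity * sig


class TestSensorModel:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            sg.SensorModel(k_slope=0.0)
        with pytest.raises(ValueError):
            sg.SensorModel(frac_fast=1.5)
        with pytest.raises(ValueError):
            sg.SensorModel(tau_fast=0.5, tau_slow=0.1)

    def test_null_targeting_forces_zero_sensitivity(self):
        m = sg.SensorModel(df_max=0.4, targeting="null")
        assert m.df_max == 0.0

    def test_monotone_decreasing_for_negative_polarity(self):
        m = sg.default_sensor("st")
        v = np.linspace(-150, 80, 500)
        f = m.steady_state(v)
        assert np.all(np.diff(f) <= 0)

    def test_monotone_increasing_for_positive_polarity(self):
        m = sg.SensorModel(polarity=+1)
        f = m.steady_state(np.linspace(-150, 80, 500))
        assert np.all(np.diff(f) >= 0)

    def test_default_sensitivity_near_printed_regime(self):
        # local slope at rest close to -0.19 %dF/F per mV (back-derived value)
        m = sg.default_sensor("st")
        assert -0.21 < m.slope_at(-68.5) < -0.17


class TestSensorFluorescence:
    def test_resting_vm_gives_constant_output(self, nobleach_sensor):
        vm = np.full(3000, -68.5)
        f = sg.sensor_fluorescence(vm, nobleach_sensor)
        assert np.allclose(f, f[0])

    def test_step_steady_state_matches_boltzmann_oracle(self, nobleach_sensor):
        vm = np.full(4000, -70.0)
        vm[500:] = -50.0
        f = sg.sensor_fluorescence(vm, nobleach_sensor)
        dff = (f[-1] - f[499]) / f[499]
        expected = (boltzmann_oracle(-50.0, nobleach_sensor)
                    - boltzmann_oracle(-70.0, nobleach_sensor)) \
            / boltzmann_oracle(-70.0, nobleach_sensor)
        assert np.isclose(dff, expected, rtol=1e-3)
        assert dff < 0

    def test_locally_linear_regime_matches_slope_prediction(self):
        # configured so slope(-70) = -0.19 %dF/F per mV in a near-linear region:
        # a 20 mV step then lands near -3.8% dF/F
        m = sg.SensorModel(v_half=-30.0, k_slope=100.0, df_max=0.601,
                           tau_bleach=np.inf)
        assert np.isclose(m.slope_at(-70.0), -0.19, atol=0.005)
        vm = np.full(4000, -70.0)
        vm[500:] = -50.0
        f = sg.sensor_fluorescence(vm, m)
        dff = (f[-1] - f[499]) / f[499]
        assert np.isclose(dff, -0.038, rtol=0.05)

    def test_st_larger_response_than_mt_for_20mv_step(self):
        vm = np.full(4000, -70.0)
        vm[500:] = -50.0
        resp = {}
        for name in ("st", "mt"):
            m = sg.default_sensor(name)
            m = sg.SensorModel(v_half=m.v_half, k_slope=m.k_slope, df_max=m.df_max,
                               tau_bleach=np.inf)
            f = sg.sensor_fluorescence(vm, m)
            resp[name] = abs((f[-1] - f[499]) / f[499])
        assert resp["st"] > resp["mt"]

    def test_null_sensor_ignores_voltage(self):
        m = sg.SensorModel(targeting="null", tau_bleach=np.inf)
        vm = -68.5 + 30 * np.sin(np.linspace(0, 20, 5000))
        f = sg.sensor_fluorescence(vm, m)
        assert np.allclose(f, 1.0)

    def test_bleach_multiplies_output(self):
        m = sg.SensorModel(tau_bleach=10.0)
        vm = np.full(20_000, -68.5)
        f = sg.sensor_fluorescence(vm, m)
        t = np.arange(vm.size) / 1000.0
        assert np.allclose(f / f[0], np.exp(-(t - t[0]) / 10.0), rtol=1e-6)

    def test_nonfinite_vm_rejected(self, st_sensor):
        vm = np.full(100, -70.0)
        vm[5] = np.inf
        with pytest.raises(ValueError):
            sg.sensor_fluorescence(vm, st_sensor)


class TestCalciumFluorescence:
    def test_no_spikes_flat(self):
        vm = np.full(2000, -68.5)
        f = sg.calcium_fluorescence([], vm, sg.CalciumModel())
        assert np.allclose(f, 1.0)

    def test_burst_amplitude_linear_in_spike_count(self):
        c = sg.CalciumModel()
        vm = np.full(5000, -68.5)
        one = sg.calcium_fluorescence([1.0], vm, c)
        three = sg.calcium_fluorescence([1.0, 1.0, 1.0], vm, c)
        ratio = (three.max() - 1.0) / (one.max() - 1.0)
        assert abs(ratio - 3.0) < 0.03

    def test_peak_at_closed_form_kernel_maximum(self):
        c = sg.CalciumModel(tau_rise=0.02, tau_decay=0.4)
        # closed form: t* = tr*td/(td-tr) * ln(td/tr)
        t_star = 0.02 * 0.4 / (0.4 - 0.02) * math.log(0.4 / 0.02)
        vm = np.full(3000, -68.5)
        f = sg.calcium_fluorescence([1.0], vm, c)
        t_peak = np.argmax(f) / 1000.0 - 1.0
        assert abs(t_peak - t_star) < 0.002
        assert abs(t_star - c.peak_delay) < 1e-12

    def test_spike_outside_duration_rejected(self):
        vm = np.full(1000, -68.5)
        with pytest.raises(ValueError):
            sg.calcium_fluorescence([5.0], vm, sg.CalciumModel())

    def test_invariants(self):
        with pytest.raises(ValueError):
            sg.CalciumModel(a_spike=-0.1)
        with pytest.raises(ValueError):
            sg.CalciumModel(tau_rise=0.5, tau_decay=0.4)


class TestSimulatePopulationVoltage:
    def test_no_drive_constant_at_rest(self, tiny_scene):
        dyn = sg.VoltageDynamics(up_rate=0.0, epsp_rate=0.0)
        pop = sg.simulate_population_voltage(dyn, tiny_scene, [], 10.0, seed=0)
        assert np.allclose(pop.vm, dyn.v_rest)
        assert all(s.size == 0 for s in pop.spike_times)

    def test_evoked_peak_in_expected_window(self, tiny_scene):
        dyn = sg.VoltageDynamics(up_rate=0.0, epsp_rate=0.0, evoked_latency=0.04,
                                 spike_prob_per_up=0.0)
        pop = sg.simulate_population_voltage(dyn, tiny_scene, [1.0], 3.0, seed=1)
        # oracle: analytic kernel-peak location after onset
        decay_tau = dyn.up_dur / 3.0
        t_pk = sg.event_kernel_peak_delay(decay_tau)
        assert 0.0 < t_pk < 0.06
        for c in range(pop.n_cells):
            peak_t = pop.t[np.argmax(pop.vm[c])]
            assert 1.03 <= peak_t <= 1.10

    def test_same_seed_bit_identical(self, tiny_scene):
        dyn = sg.VoltageDynamics()
        a = sg.simulate_population_voltage(dyn, tiny_scene, [2.0], 20.0, seed=7)
        b = sg.simulate_population_voltage(dyn, tiny_scene, [2.0], 20.0, seed=7)
        assert np.array_equal(a.vm, b.vm)
        for sa, sb in zip(a.spike_times, b.spike_times):
            assert np.array_equal(sa, sb)

    def test_different_seeds_differ(self, tiny_scene):
        dyn = sg.VoltageDynamics()
        a = sg.simulate_population_voltage(dyn, tiny_scene, [], 20.0, seed=1)
        b = sg.simulate_population_voltage(dyn, tiny_scene, [], 20.0, seed=2)
        assert not np.array_equal(a.vm, b.vm)

    def test_stimulus_outside_duration_rejected(self, tiny_scene):
        with pytest.raises(ValueError):
            sg.simulate_population_voltage(sg.VoltageDynamics(), tiny_scene,
                                           [11.0], 10.0, seed=0)

    def test_spikes_only_on_threshold_crossings(self, tiny_scene):
        dyn = sg.VoltageDynamics(up_rate=0.3, spike_prob_per_up=1.0)
        pop = sg.simulate_population_voltage(dyn, tiny_scene, [], 60.0, seed=3)
        for c, spikes in enumerate(pop.spike_times):
            assert spikes.size > 0
            assert np.all(np.diff(spikes) > 0)

    def test_ground_truth_events_sorted(self, tiny_scene):
        pop = sg.simulate_population_voltage(sg.VoltageDynamics(), tiny_scene,
                                             [], 30.0, seed=5)
        for c in range(pop.n_cells):
            onsets = [e["onset"] for e in pop.events if e["roi"] == f"cell_{c:03d}"]
            assert onsets == sorted(onsets)


@pytest.fixture(scope="module")
def episode():
    scene = sg.default_scene(n_cells=6, seed=0)
    dyn = sg.VoltageDynamics(epsp_rate=0.0)
    sz = sg.SeizureConfig(preictal_window=30.0, focus_offset=500.0)
    return sg.simulate_seizure_episode(dyn, scene, sz, 45.0, seed=11), scene, sz


class TestSimulateSeizureEpisode:

    def test_zero_coupling_leaves_imaged_cells_unperturbed(self):
        scene = sg.default_scene(n_cells=4, seed=1)
        dyn = sg.VoltageDynamics(epsp_rate=0.0)
        sz = sg.SeizureConfig(preictal_window=30.0, iis_coupling_ramp=0.0)
        ep = sg.simulate_seizure_episode(dyn, scene, sz, 45.0, seed=2)
        pre = ep.population.vm[:, : int(25.0 * sg.VM_RATE)]
        assert np.allclose(pre, dyn.v_rest, atol=1e-6)

    def test_recruitment_times_follow_distance_over_speed(self):
        scene = sg.ScenePlan(np.array([[10.0, 50.0], [110.0, 50.0]]),
                             soma_radius=8.0, fov=(128.0, 128.0))
        dyn = sg.VoltageDynamics(epsp_rate=0.0)
        sz = sg.SeizureConfig(preictal_window=10.0, focus_offset=1000.0,
                              wavefront_speed=100.0)
        ep = sg.simulate_seizure_episode(dyn, scene, sz, 25.0, seed=3)
        rec = ep.ground_truth.recruitment_times
        assert np.isclose(rec[1] - rec[0], 1.0, atol=1e-9)

    def test_subthreshold_onsets_tighter_than_recruitment(self, episode):
        ep, _, _ = episode
        gt = ep.ground_truth
        assert np.std(gt.subthreshold_onsets) < np.std(gt.recruitment_times)

    def test_recruitment_after_lfp_onset(self, episode):
        ep, _, _ = episode
        gt = ep.ground_truth
        assert np.all(gt.recruitment_times >= gt.lfp_onset)
        assert np.all(gt.subthreshold_onsets >= gt.lfp_onset)

    def test_iis_coupling_grows_toward_onset(self, episode):
        ep, _, _ = episode
        assert np.all(np.diff(ep.iis_coupling) >= 0)
        assert ep.iis_coupling[0] == 0.0

    def test_invalid_wavefront_speed(self):
        with pytest.raises(ValueError):
            sg.SeizureConfig(wavefront_speed=0.0)

    def test_duration_must_cover_ictal_period(self, tiny_scene):
        with pytest.raises(ValueError):
            sg.simulate_seizure_episode(sg.VoltageDynamics(), tiny_scene,
                                        sg.SeizureConfig(preictal_window=40.0),
                                        40.5, seed=0)


class TestRenderDualChannelMovie:
    def _static_inputs(self, scene, value=1.0, duration=4.0):
        n = int(duration * sg.VM_RATE)
        volt = np.full((scene.n_cells, n), value)
        ca = np.full((scene.n_cells, n), value)
        return volt, ca

    def test_noise_free_static_cell_preserves_trace(self):
        scene = sg.ScenePlan(np.array([[64.0, 64.0]]), soma_radius=12.0,
                             neuropil_level=0.0, fov=(128.0, 128.0))
        n = int(4.0 * sg.VM_RATE)
        ramp = 1.0 + 0.2 * np.sin(2 * np.pi * 0.5 * np.arange(n) / sg.VM_RATE)
        noise = sg.NoiseModel(heartbeat_amp=0.0, photon_scale=0.0, motion_sd=0.0,
                              psf_sigma=0.0)
        sv, _, _ = sg.render_dual_channel_movie(ramp[None], ramp[None], scene,
                                                noise, seed=0)
        masks = scene.cell_masks()
        soma_trace = sv.data[:, masks[0]].mean(axis=1)
        binned = sg._bin_to_frames(ramp[None], sg.VM_RATE, 30.0)[0]
        scaled = soma_trace / soma_trace[0]
        assert np.allclose(scaled, binned / binned[0], atol=2e-3)

    def test_heartbeat_peak_in_power_spectrum(self):
        scene = sg.default_scene(n_cells=4, seed=0)
        volt, ca = self._static_inputs(scene, duration=20.0)
        noise = sg.NoiseModel(heartbeat_amp=0.01, heartbeat_freq=7.0,
                              photon_scale=0.0, motion_sd=0.0)
        sv, _, _ = sg.render_dual_channel_movie(volt, ca, scene, noise, seed=0)
        fov = sv.data.mean(axis=(1, 2))
        fov = fov - fov.mean()
        freqs = np.fft.rfftfreq(fov.size, 1 / 30.0)
        power = np.abs(np.fft.rfft(fov)) ** 2
        band = (freqs > 0.5) & (freqs < 14.0)
        assert np.isclose(freqs[band][np.argmax(power[band])], 7.0, atol=0.2)

    def test_same_seed_identical_stacks(self, tiny_scene):
        volt, ca = self._static_inputs(tiny_scene)
        noise = sg.NoiseModel()
        a = sg.render_dual_channel_movie(volt, ca, tiny_scene, noise, seed=5)
        b = sg.render_dual_channel_movie(volt, ca, tiny_scene, noise, seed=5)
        assert np.array_equal(a[0].data, b[0].data)
        assert np.array_equal(a[1].data, b[1].data)
        assert np.array_equal(a[2], b[2])

    def test_flash_frames_saturated(self, tiny_scene):
        volt, ca = self._static_inputs(tiny_scene)
        noise = sg.NoiseModel(flash_frames=(5, 6))
        sv, sc, _ = sg.render_dual_channel_movie(volt, ca, tiny_scene, noise, seed=0)
        assert np.all(sv.data[5] == sg.FULL_SCALE)
        assert np.all(sc.data[6] == sg.FULL_SCALE)

    def test_flash_frame_out_of_range_rejected(self, tiny_scene):
        volt, ca = self._static_inputs(tiny_scene)
        noise = sg.NoiseModel(flash_frames=(10_000,))
        with pytest.raises(ValueError):
            sg.render_dual_channel_movie(volt, ca, tiny_scene, noise, seed=0)

    def test_mismatched_traces_rejected(self, tiny_scene):
        volt, _ = self._static_inputs(tiny_scene)
        with pytest.raises(ValueError):
            sg.render_dual_channel_movie(volt, volt[:, :-5], tiny_scene,
                                         sg.NoiseModel(), seed=0)


class TestSynthesizeLfp:
    def test_silent_population_flat(self):
        vm = np.full((3, 5000), -68.5)
        lfp = sg.synthesize_lfp(vm)
        assert np.allclose(lfp.y, 0.0)

    def test_synchronous_depolarisation_negative_deflection(self):
        vm = np.full((4, 5000), -68.5)
        vm[:, 2000:2500] += 20.0
        lfp = sg.synthesize_lfp(vm)
        assert lfp.y.min() < -10.0
        assert np.argmin(lfp.y) in range(2000, 2500)
        assert np.allclose(lfp.y[:1900], 0.0)

    def test_sample_count(self):
        vm = np.full((2, 10_000), -68.5)
        assert sg.synthesize_lfp(vm).y.size == 10_000

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            sg.synthesize_lfp(np.empty((0, 100)))


class TestScenePlan:
    def test_cells_must_be_inside_fov(self):
        with pytest.raises(ValueError):
            sg.ScenePlan(np.array([[200.0, 10.0]]), fov=(128.0, 128.0))

    def test_shape_from_fov_and_pixel_size(self, tiny_scene):
        assert tiny_scene.shape == (64, 64)

    def test_default_scene_respects_count(self):
        scene = sg.default_scene(n_cells=13, seed=0)
        assert scene.n_cells == 13
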