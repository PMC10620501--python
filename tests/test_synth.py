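"""Forward-model simulator: event statistics, rendering physics, traces."""

import math

import numpy as np
import pytest

from azlmquant import (GroundTruth, GroundTruthEvent, NoiseConfig, OpticsConfig,
                       expected_exo_count, make_timeline, render_stack,
                       simulate_events, simulate_ph_trace,
                       simulate_single_molecule_traces, simulate_stimulus_traces,
                       simulate_ztip_series)
from azlmquant.calibrate import measure_exchange_time

NOISELESS = NoiseConfig(photon_scale=0.0, read_noise_sd=0.0, background_level=50.0)


class TestSimulateEvents:
    def test_zero_pulses_empty(self):
        assert simulate_events(0, seed=0).events == []

    def test_no_ufe_at_room_temperature(self):
        for seed in range(10):
            gt = simulate_events(50, temperature_C=22.0, seed=seed,
                                 mode_mix={"CME": 0.3, "ADBE": 0.3, "UFE": 0.4})
            assert all(e.mode != "UFE" for e in gt.events)

    def test_ufe_present_and_subsecond_at_pt(self):
        stim_end_offsets = []
        for seed in range(20):
            gt = simulate_events(5, temperature_C=31.5, seed=seed, stim_onset=0.0)
            for e in gt.events:
                if e.mode == "UFE":
                    stim_end_offsets.append(e.t_event - 5 / 50.0)
        assert stim_end_offsets, "no UFE events over 20 seeds at PT"
        assert all(0 <= d < 0.3 for d in stim_end_offsets)

    def test_saturation_sublinear_at_125_pulses(self):
        # saturation formula: E[N(125)]/E[N(50)] below the linear ratio 2.5
        assert expected_exo_count(125) / expected_exo_count(50) < 125 / 50

    def test_expected_count_monotone_and_concave(self):
        p = np.arange(0, 200, 5)
        n = np.array([expected_exo_count(v) for v in p])
        assert np.all(np.diff(n) > 0)
        assert np.all(np.diff(n, 2) < 1e-12)

    def test_negative_pulses_rejected(self):
        with pytest.raises(ValueError):
            simulate_events(-1, seed=0)

    def test_mode_mix_must_normalize(self):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_events(50, mode_mix={"CME": 0.5, "ADBE": 0.2, "UFE": 0.0},
                            seed=0)

    def test_endo_events_ring_around_edge(self):
        radii = []
        for seed in range(10):
            gt = simulate_events(50, seed=seed)
            radii += [math.hypot(*e.xy_nm) - gt.azlm_radius_nm
                      for e in gt.events if e.kind == "endo"]
        assert radii
        assert abs(np.mean(radii) - 100.0) < 80.0  # annulus centred ~100 nm out

    def test_determinism(self):
        a = simulate_events(50, seed=7)
        b = simulate_events(50, seed=7)
        assert a.to_dict() == b.to_dict()


class TestRenderStack:
    def test_no_events_noise_off_is_flat_background(self):
        tl = make_timeline(0.12, 0.36)
        stack = render_stack(GroundTruth(), tl, OpticsConfig(), NOISELESS,
                             "SEP", shape=(32, 32))
        np.testing.assert_allclose(stack.pixels, 50.0)

    def test_surface_fluorophore_fully_quenched_at_ph6(self):
        tl = make_timeline(0.12, 0.48, ph6_starts=[0.2], ph6_duration=0.25)
        gt = GroundTruth(events=[GroundTruthEvent(
            kind="exo", mode="none", t_event=0.0, xy_nm=(0.0, 0.0), z_nm=0.0,
            amplitude_molecules=10.0, diffusion_sigma_rate=0.0)])
        optics = OpticsConfig(quench_residual=0.0, sep_brightness_rt=100.0)
        stack = render_stack(gt, tl, optics, NOISELESS, "SEP", shape=(32, 32))
        ph = np.asarray(tl.ph_at(tl.frame_times))
        acid = stack.pixels[ph == 6.0]
        neutral = stack.pixels[ph == 7.4]
        np.testing.assert_allclose(acid, 50.0)        # fully quenched
        assert neutral.sum() > acid.sum()

    def test_axial_attenuation_closed_form(self):
        """An endocytosed vesicle at z = 150 nm under a 151 nm depth constant
        contributes exp(-150/151) ~ 0.37 of its amplitude."""
        tl = make_timeline(0.12, 0.12)
        gt = GroundTruth(events=[GroundTruthEvent(
            kind="endo", mode="CME", t_event=0.0, xy_nm=(0.0, 0.0), z_nm=150.0,
            amplitude_molecules=1.0)])
        optics = OpticsConfig(tirf_depth_nm=151.0, sep_brightness_rt=1000.0)
        stack = render_stack(gt, tl, optics, NOISELESS, "SEP", shape=(48, 48))
        integrated = (stack.pixels[0] - 50.0).sum()
        assert integrated == pytest.approx(1000.0 * math.exp(-150.0 / 151.0),
                                           rel=1e-6)

    def test_cast_channel_static_disc_only(self):
        tl = make_timeline(0.12, 0.36)
        gt = GroundTruth(events=[GroundTruthEvent(
            kind="endo", mode="CME", t_event=0.0, xy_nm=(400.0, 0.0), z_nm=0.0,
            amplitude_molecules=50.0)])
        stack = render_stack(gt, tl, OpticsConfig(), NOISELESS, "CAST",
                             shape=(32, 32), cast_amplitude=200.0)
        np.testing.assert_allclose(stack.pixels[0], stack.pixels[1])
        assert stack.pixels[0].max() > 50.0

    def test_bit_identical_for_same_seed(self):
        tl = make_timeline(0.12, 0.6)
        noise = NoiseConfig(photon_scale=10.0, read_noise_sd=20.0,
                            background_level=100.0, background_texture_sd=25.0)
        gt = simulate_events(50, seed=3)
        a = render_stack(gt, tl, OpticsConfig(), noise, "SEP", seed=42)
        b = render_stack(gt, tl, OpticsConfig(), noise, "SEP", seed=42)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_puncta_count_conserved_noiseless(self):
        """With noise off and well-separated events, supra-threshold puncta in
        a pH 6.0 frame equal the ground-truth count of visible vesicles."""
        from conftest import flood_components
        tl = make_timeline(0.12, 0.48, ph6_starts=[0.2], ph6_duration=0.25)
        events = [GroundTruthEvent(kind="endo", mode="CME", t_event=0.0,
                                   xy_nm=xy, z_nm=100.0, amplitude_molecules=5.0)
                  for xy in [(-700.0, -700.0), (700.0, -500.0), (0.0, 900.0)]]
        gt = GroundTruth(events=events)
        stack = render_stack(gt, tl, OpticsConfig(sep_brightness_rt=1000.0),
                             NOISELESS, "SEP", shape=(48, 48))
        ph = np.asarray(tl.ph_at(tl.frame_times))
        frame = stack.pixels[ph == 6.0][0]
        comps = flood_components(frame > 50.0 + 100.0)
        assert len(comps) == 3


class TestTraces:
    def test_noiseless_single_step_exact(self):
        tr = simulate_single_molecule_traces(5, 2900.0, 0.0, 50, seed=0)
        for t in tr:
            levels = set(np.round(t, 6))
            assert levels == {0.0, 2900.0}
            drops = np.nonzero(np.diff(t) < 0)[0]
            assert len(drops) == 1

    def test_zero_amplitude_flat(self):
        tr = simulate_single_molecule_traces(3, 0.0, 0.0, 20, seed=0)
        np.testing.assert_allclose(tr, 0.0)

    def test_trace_determinism(self):
        a = simulate_single_molecule_traces(10, 2900.0, 80.0, 100, seed=5)
        b = simulate_single_molecule_traces(10, 2900.0, 80.0, 100, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_ztip_closed_form(self):
        z, i = simulate_ztip_series(151.0, [0.0, 151.0], 0.0, i0=1000.0)
        assert i[0] == pytest.approx(1000.0)
        assert i[1] == pytest.approx(1000.0 / math.e)

    def test_ztip_protocol_grid(self):
        z, _ = simulate_ztip_series(151.0, np.arange(0, 626, 125), 0.0)
        np.testing.assert_array_equal(z, [0, 125, 250, 375, 500, 625])

    def test_ztip_rejects_negative_z(self):
        with pytest.raises(ValueError):
            simulate_ztip_series(151.0, [-10.0])

    def test_stimulus_trace_shape(self):
        t, tr = simulate_stimulus_traces(2, 1000.0, 20.0, noise_frac=0.0)
        assert tr.shape == (2, t.size)
        peak_idx = np.argmax(tr[0])
        assert t[peak_idx] == pytest.approx(5.0)


class TestPhTrace:
    def test_exchange_durations_match_configuration(self):
        tl = make_timeline(0.12, 6.0, ph6_starts=[3.0], ph6_duration=0.7)
        t, v = simulate_ph_trace(tl, exchange_down_ms=100.0, exchange_up_ms=200.0)
        assert measure_exchange_time(t, v, "down") == pytest.approx(100.0, abs=0.5)
        assert measure_exchange_time(t, v, "up") == pytest.approx(200.0, abs=0.5)

    def test_no_window_constant(self):
        tl = make_timeline(0.12, 2.0)
        _, v = simulate_ph_trace(tl)
        np.testing.assert_allclose(v, 1.0)

    def test_invalid_exchange_times(self):
        tl = make_timeline(0.12, 2.0)
        with pytest.raises(ValueError):
            simulate_ph_trace(tl, exchange_down_ms=0.0)
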