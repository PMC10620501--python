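"""Window averaging, subtraction, centroids, distances, metrics, time courses."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from azlmquant import (AnalysisConfig, average_ph6_window, cluster_metrics,
                       exo_endo_correlation, fit_decay_constant,
                       flag_influx_exclusion, intensity_centroid,
                       make_timeline, membrane_area_ratio,
                       nearest_centroid_displacement, normalized_timecourse,
                       signed_edge_distance, subtract_prestim,
                       temperature_correct)
from azlmquant.segment import AZLMRegion, SignalCluster, boundary_mask
from conftest import brute_centroid, brute_edge_distance, gaussian_blob

PX = 66.7


def _azlm_from_mask(mask):
    return AZLMRegion(label=1, mask=mask, area_um2=mask.sum() * (PX / 1000) ** 2,
                      centroid_nm=(0.0, 0.0), boundary=boundary_mask(mask))


def _cluster_from_mask(mask, area=1.0):
    return SignalCluster(label=1, mask=mask, area_um2=area, centroid_nm=(0, 0),
                         max_intensity=0.0, sum_intensity=0.0)


class TestWindowAveraging:
    def test_later_four_of_five_frames(self):
        tl = make_timeline(0.12, 6.0, ph6_starts=[3.0], ph6_duration=0.7)
        pixels = np.zeros((tl.n_frames, 4, 4))
        idx = tl.frames_in_window(tl.acid_windows()[0])
        for v, i in enumerate(idx, start=1):
            pixels[i] = float(v)  # frames valued 1..5
        img, label = average_ph6_window(pixels, tl, tl.acid_windows()[0])
        np.testing.assert_allclose(img, (2 + 3 + 4 + 5) / 4.0)
        assert label == pytest.approx(3.24)

    def test_constant_frames_preserved(self):
        tl = make_timeline(0.12, 6.0, ph6_starts=[3.0], ph6_duration=0.7)
        pixels = np.full((tl.n_frames, 4, 4), 7.0)
        img, _ = average_ph6_window(pixels, tl, tl.acid_windows()[0])
        np.testing.assert_allclose(img, 7.0)

    def test_short_window_rejected(self):
        tl = make_timeline(0.12, 6.0, ph6_starts=[3.0], ph6_duration=0.3)
        pixels = np.zeros((tl.n_frames, 4, 4))
        with pytest.raises(ValueError, match="required"):
            average_ph6_window(pixels, tl, tl.acid_windows()[0])


class TestSubtraction:
    def test_identical_images_zero(self):
        img = np.random.default_rng(0).normal(size=(8, 8))
        np.testing.assert_allclose(subtract_prestim(img, img), 0.0)

    def test_punctum_survives_static_cancels(self):
        static = gaussian_blob((32, 32), 10, 10, 3.0, 500.0)  # organelle
        punctum = gaussian_blob((32, 32), 20, 22, 2.0, 300.0)
        diff = subtract_prestim(static + punctum, static)
        np.testing.assert_allclose(diff, punctum, atol=1e-9)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            subtract_prestim(np.zeros((8, 8)), np.zeros((9, 8)))

    def test_average_then_subtract_cancels_added_static(self):
        tl = make_timeline(0.12, 6.0, ph6_starts=[1.0, 3.0], ph6_duration=0.7)
        rng = np.random.default_rng(2)
        pixels = rng.uniform(0, 10, size=(tl.n_frames, 8, 8))
        static = rng.uniform(0, 100, size=(8, 8))
        w_pre, w_post = tl.acid_windows()
        a_pre, _ = average_ph6_window(pixels, tl, w_pre)
        a_post, _ = average_ph6_window(pixels, tl, w_post)
        b_pre, _ = average_ph6_window(pixels + static, tl, w_pre)
        b_post, _ = average_ph6_window(pixels + static, tl, w_post)
        np.testing.assert_allclose(subtract_prestim(a_post, a_pre),
                                   subtract_prestim(b_post, b_pre), atol=1e-9)


class TestInfluxExclusion:
    def test_rising_ramp_excluded(self):
        assert flag_influx_exclusion([0.0, 10.0, 20.0, 30.0, 40.0], 1.0)

    def test_flat_trace_retained(self):
        assert not flag_influx_exclusion([5.0, 5.0, 5.0, 5.0, 5.0], 1.0)

    def test_decaying_trace_retained(self):
        assert not flag_influx_exclusion([40.0, 30.0, 20.0, 10.0], 1.0)

    def test_requires_four_samples(self):
        with pytest.raises(ValueError):
            flag_influx_exclusion([1.0, 2.0, 3.0], 1.0)


class TestCentroid:
    def test_single_lit_pixel(self):
        frame = np.zeros((12, 12))
        frame[5, 7] = 9.0
        mask = frame > 0
        cy, cx = intensity_centroid(frame, mask, PX)
        assert (cy, cx) == (pytest.approx(5 * PX), pytest.approx(7 * PX))

    def test_weighted_two_pixel(self):
        # x-indices 0 (weight 1) and 2 (weight 3) -> centroid at index 1.5
        frame = np.zeros((3, 3))
        frame[1, 0], frame[1, 2] = 1.0, 3.0
        mask = frame > 0
        _, cx = intensity_centroid(frame, mask, PX)
        assert cx == pytest.approx(1.5 * PX)

    def test_symmetric_gaussian_centered(self):
        frame = gaussian_blob((21, 21), 10.0, 10.0, 2.0, 100.0)
        cy, cx = intensity_centroid(frame, frame > 1.0, PX)
        assert cy == pytest.approx(10 * PX, abs=1e-6)
        assert cx == pytest.approx(10 * PX, abs=1e-6)

    def test_zero_intensity_rejected(self):
        frame = np.zeros((4, 4))
        mask = np.ones((4, 4), bool)
        with pytest.raises(ValueError):
            intensity_centroid(frame, mask, PX)

    def test_matches_brute_force(self, rng):
        frame = rng.uniform(0.1, 5.0, size=(16, 16))
        mask = rng.uniform(size=(16, 16)) > 0.6
        mask[0, 0] = True
        got = intensity_centroid(frame, mask, PX)
        want = brute_centroid(frame, mask, PX)
        np.testing.assert_allclose(got, want)


class TestSignedEdgeDistance:
    def _disc(self, radius_nm, shape=(49, 49)):
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]] * PX
        cy = cx = (shape[0] // 2) * PX  # disc centred on a pixel centre
        mask = np.hypot(yy - cy, xx - cx) <= radius_nm
        return _azlm_from_mask(mask), (cy, cx)

    def test_disc_centre_is_minus_radius(self):
        # boundary pixels are member-pixel centres: discretization error up
        # to one pixel for interior points on a jagged discrete circle
        azlm, centre = self._disc(300.0)
        d = signed_edge_distance(centre, azlm, PX)
        assert d.signed_nm == pytest.approx(-300.0, abs=PX)
        assert d.signed_nm < 0

    def test_outside_point_positive(self):
        azlm, (cy, cx) = self._disc(300.0)
        d = signed_edge_distance((cy, cx + 400.0), azlm, PX)
        assert d.signed_nm == pytest.approx(100.0, abs=PX)
        assert d.signed_nm > 0

    def test_on_boundary_within_half_pixel(self):
        azlm, _ = self._disc(300.0)
        r, c = map(lambda a: a[0], np.nonzero(azlm.boundary))
        d = signed_edge_distance((r * PX, c * PX), azlm, PX)
        assert abs(d.signed_nm) <= PX / 2 + 1e-9

    def test_matches_brute_force_on_random_masks(self, rng):
        from skimage.measure import label as sk_label
        for _ in range(10):
            mask = rng.uniform(size=(20, 20)) > 0.7
            labels = sk_label(mask, connectivity=2)
            if labels.max() == 0:
                continue
            biggest = labels == np.argmax(np.bincount(labels.ravel())[1:]) + 1
            azlm = _azlm_from_mask(biggest)
            centroid = (rng.uniform(0, 19) * PX, rng.uniform(0, 19) * PX)
            got = signed_edge_distance(centroid, azlm, PX).signed_nm
            want = brute_edge_distance(centroid, biggest, PX)
            assert got == pytest.approx(want)

    def test_empty_boundary_rejected(self):
        azlm = AZLMRegion(1, np.zeros((4, 4), bool), 0.0, (0, 0),
                          np.zeros((4, 4), bool))
        with pytest.raises(ValueError):
            signed_edge_distance((0.0, 0.0), azlm, PX)


class TestClusterMetrics:
    def test_single_pixel_density(self):
        frame = np.zeros((5, 5))
        frame[2, 2] = 10.0
        mask = frame > 0
        area = (PX / 1000) ** 2
        c = _cluster_from_mask(mask, area=area)
        max_i, a, dens = cluster_metrics(frame, c)
        assert (max_i, a) == (10.0, area)
        assert dens == pytest.approx(10.0 / area)

    def test_intensity_homogeneity(self, rng):
        frame = rng.uniform(1, 10, size=(12, 12))
        mask = rng.uniform(size=(12, 12)) > 0.5
        mask[3, 3] = True
        c = _cluster_from_mask(mask, area=0.3)
        m1, a1, d1 = cluster_metrics(frame, c)
        m2, a2, d2 = cluster_metrics(2.0 * frame, c)
        assert m2 == pytest.approx(2 * m1)
        assert a2 == a1
        assert d2 == pytest.approx(2 * d1)


class TestTemperatureCorrection:
    def test_published_rescaling(self):
        """The PT density 8.3 rescaled by the RT/PT single-molecule brightness
        ratio gives 10.9 (one decimal)."""
        assert round(temperature_correct(8.3, 2900.0, 2200.0), 1) == 10.9

    def test_unit_ratio_identity(self):
        assert temperature_correct(5.0, 1000.0, 1000.0) == 5.0

    def test_calibration_value_maps_to_calibration(self):
        assert temperature_correct(2200.0, 2900.0, 2200.0) == pytest.approx(2900.0)

    @given(st.floats(min_value=0.1, max_value=100.0),
           st.floats(min_value=100.0, max_value=5000.0),
           st.floats(min_value=100.0, max_value=5000.0))
    def test_round_trip_inverse(self, value, i_rt, i_pt):
        back = temperature_correct(temperature_correct(value, i_rt, i_pt),
                                   i_pt, i_rt)
        assert back == pytest.approx(value, rel=1e-12)

    def test_non_positive_calibration_rejected(self):
        with pytest.raises(ValueError):
            temperature_correct(1.0, 0.0, 2200.0)


class TestDisplacement:
    def test_identical_sets_zero(self):
        pts = [(0.0, 0.0), (100.0, 50.0)]
        np.testing.assert_allclose(nearest_centroid_displacement(pts, pts), 0.0)

    def test_three_four_five(self):
        d = nearest_centroid_displacement([(0.0, 0.0)], [(300.0, 400.0)])
        assert d[0] == pytest.approx(500.0)

    def test_nearest_neighbour_wins(self):
        d = nearest_centroid_displacement([(0.0, 0.0)],
                                          [(100.0, 0.0), (1000.0, 0.0)])
        assert d[0] == pytest.approx(100.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            nearest_centroid_displacement([(0.0, 0.0)], np.empty((0, 2)))


class TestTimecourse:
    def _timeline(self):
        return make_timeline(0.12, 12.0, stim_onset=6.0, n_pulses=50,
                             ph6_starts=[1.08, 9.0], ph6_duration=0.7)

    def test_normalized_peak(self):
        tl = self._timeline()
        trace = np.full(tl.n_frames, 1000.0)
        trace[tl.frame_times > 6.0] = 3000.0
        out = normalized_timecourse(trace, tl)
        assert max(m.normalized_f for m in out) == pytest.approx(3.0)

    def test_baseline_delta_zero(self):
        tl = self._timeline()
        trace = np.full(tl.n_frames, 1000.0)
        out = normalized_timecourse(trace, tl)
        assert all(m.delta_f == pytest.approx(0.0) for m in out)
        assert all(m.normalized_f == pytest.approx(1.0) for m in out)

    def test_pulse_scaling_near_linear_regime(self):
        """With the saturating release model, simulated peak amplitudes for
        5/20/50 pulses stay near the 1:4:10 proportionality."""
        from azlmquant import expected_exo_count
        n5, n20, n50 = (expected_exo_count(p) for p in (5, 20, 50))
        assert n20 / n5 == pytest.approx(4.0, rel=0.15)
        assert n50 / n5 == pytest.approx(10.0, rel=0.2)

    def test_requires_prestim_frames(self):
        tl = make_timeline(0.12, 2.0, stim_onset=0.0)
        with pytest.raises(ValueError):
            normalized_timecourse(np.ones(tl.n_frames), tl)


class TestDecayFit:
    @pytest.mark.parametrize("tau", [20.0, 5.0])
    def test_noiseless_recovery(self, tau):
        t = np.arange(0, 40, 0.5)
        y = 1000.0 * np.exp(-np.clip(t - 5.0, 0, None) / tau)
        assert fit_decay_constant(t, y, 5.0) == pytest.approx(tau, rel=1e-6)

    def test_simulated_traces_within_10pct(self):
        from azlmquant import simulate_stimulus_traces
        t, traces = simulate_stimulus_traces(50, 1000.0, 20.0, noise_frac=0.02,
                                             seed=11)
        taus = [fit_decay_constant(t, y, 5.0) for y in traces]
        assert np.mean(taus) == pytest.approx(20.0, rel=0.1)

    def test_non_decaying_rejected(self):
        t = np.arange(0, 10, 0.5)
        with pytest.raises(ValueError):
            fit_decay_constant(t, np.linspace(1, 2, t.size), 0.0)


class TestGeometryAndCorrelation:
    def test_membrane_area_ratio_examples(self):
        assert membrane_area_ratio(100.0, 50.0) == pytest.approx(4.0)
        assert membrane_area_ratio(70.0, 70.0) == pytest.approx(1.0)
        assert membrane_area_ratio(150.0, 50.0) == pytest.approx(9.0)

    def test_membrane_area_ratio_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            membrane_area_ratio(0.0, 50.0)

    def test_perfect_linear_correlation(self):
        x = np.arange(1.0, 11.0)
        assert exo_endo_correlation(x, 2 * x) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(3)
        r = exo_endo_correlation(rng.normal(size=500), rng.normal(size=500))
        assert abs(r) < 0.15

    def test_constructed_effect_recovered(self):
        rng = np.random.default_rng(4)
        exo = rng.uniform(1000, 5000, size=100)
        endo = 0.3 * exo + rng.normal(0, 300, size=100)
        assert exo_endo_correlation(exo, endo) > 0.5

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            exo_endo_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
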