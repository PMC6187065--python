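"""Synthetic-data generator: geometry truth, rendering physics, trace models."""

import dataclasses
import math

import numpy as np
import pytest

from tatnet import simulate
from tatnet.simulate import (
    APTraceSpec,
    ImagingSpec,
    NetworkSpec,
    TransientSpec,
    generate_ap_trace,
    generate_network_geometry,
    generate_transients,
    render_image,
)

from _oracles import ribbon_profile_oracle


class TestNetworkGeometry:
    def test_pure_axial_zero_jitter_is_parallel(self):
        spec = NetworkSpec(frac_at=1.0, frac_ot=0.0, frac_tt=0.0,
                           angle_jitter_sd=0.0, junction_rate=0.0, axis_angle=0.0)
        segs = generate_network_geometry(spec, seed=3)
        for s in segs.segments:
            assert s.angle == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 7, 21])
    def test_truth_equals_independent_recomputation(self, seed, small_network_spec):
        segs = generate_network_geometry(small_network_spec, seed=seed)
        recomputed = segs.recompute_truth()
        for key, val in recomputed.items():
            assert segs.truth[key] == pytest.approx(val, rel=1e-12)
        # total length really is the sum of Euclidean segment lengths
        total = sum(math.hypot(s.x1 - s.x0, s.y1 - s.y0) for s in segs.segments)
        assert segs.truth["total_length_um"] == pytest.approx(total, rel=1e-12)

    def test_realized_fractions_track_spec(self):
        spec = NetworkSpec(frac_at=0.6, frac_ot=0.25, frac_tt=0.15,
                           cell_length=40.0, cell_width=12.0)
        fractions = []
        for seed in range(20):
            t = generate_network_geometry(spec, seed=seed).truth
            tot = t["total_length_um"]
            fractions.append([t["length_at_um"] / tot, t["length_ot_um"] / tot,
                              t["length_tt_um"] / tot])
        mean = np.mean(fractions, axis=0)
        assert np.all(np.abs(mean - [0.6, 0.25, 0.15]) <= 0.03)

    def test_deterministic_given_seed(self, small_network_spec):
        a = generate_network_geometry(small_network_spec, seed=5)
        b = generate_network_geometry(small_network_spec, seed=5)
        assert a.to_json() == b.to_json()
        c = generate_network_geometry(small_network_spec, seed=6)
        assert a.to_json() != c.to_json()

    def test_segments_inside_cell_mask(self, small_network_spec):
        segs = generate_network_geometry(small_network_spec, seed=2)
        poly = segs.cell_polygon.buffer(1e-6)
        from shapely.geometry import Point
        for s in segs.segments:
            assert poly.contains(Point(s.x0, s.y0))
            assert poly.contains(Point(s.x1, s.y1))

    def test_infeasible_density_raises(self):
        spec = NetworkSpec(target_density=5.0)
        with pytest.raises(ValueError, match="infeasible"):
            spec.validate()

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            NetworkSpec(frac_at=0.9, frac_ot=0.3, frac_tt=0.1).validate()


class TestRenderImage:
    def _single_tubule(self, width_nm=250.0):
        seg = simulate.Segment(1.0, 1.5, 4.0, 1.5, component="AT", width_nm=width_nm)
        return simulate.SegmentSet(
            segments=[seg], cell_mask_polygon=[(0, 0), (5, 0), (5, 3), (0, 3)])

    def test_empty_segments_noise_off_is_constant_background(self):
        ss = simulate.SegmentSet(segments=[],
                                 cell_mask_polygon=[(0, 0), (4, 0), (4, 2), (0, 2)])
        img, mask = render_image(ss, ImagingSpec(shot_noise=False, read_noise_sd=0.0,
                                                 background_level=37.0))
        assert np.all(img == 37)
        assert not mask.any()

    def test_cross_profile_matches_convolution_oracle(self):
        imaging = ImagingSpec(shot_noise=False, read_noise_sd=0.0,
                              background_level=10.0, tubule_peak_signal=200.0)
        img, _ = render_image(self._single_tubule(), imaging)
        col = int(2.5 / (imaging.pixel_size / 1000.0))
        profile = img[:, col].astype(float)
        oracle = ribbon_profile_oracle(
            width_nm=250.0, psf_fwhm_nm=imaging.psf_fwhm,
            pixel_size_nm=imaging.pixel_size, n_pixels=img.shape[0],
            center_nm=1500.0, background=10.0, peak=200.0)
        # within 2% of the tubule amplitude everywhere (plus quantisation)
        assert np.max(np.abs(profile - oracle)) <= 0.02 * 200.0 + 0.5

    def test_shot_noise_variance_matches_mean(self):
        ss = simulate.SegmentSet(segments=[],
                                 cell_mask_polygon=[(0, 0), (20, 0), (20, 10), (0, 10)])
        imaging = ImagingSpec(pixel_size=114.0, shot_noise=True, read_noise_sd=0.0,
                              background_level=50.0, seed=9)
        img, _ = render_image(ss, imaging)
        vals = img[:100, :100].astype(float).ravel()
        ratio = vals.var() / vals.mean()
        assert abs(ratio - 1.0) < 0.05  # Poisson: variance == mean, n = 10^4

    def test_identical_seed_identical_image(self):
        segs = self._single_tubule()
        a, _ = render_image(segs, ImagingSpec(seed=4))
        b, _ = render_image(segs, ImagingSpec(seed=4))
        assert np.array_equal(a, b)
        c, _ = render_image(segs, ImagingSpec(seed=5))
        assert not np.array_equal(a, c)

    def test_fov_smaller_than_cell_raises(self):
        with pytest.raises(ValueError, match="field of view"):
            render_image(self._single_tubule(), ImagingSpec(), fov_shape=(10, 10))

    def test_truth_mask_marks_ribbon(self):
        _, mask = render_image(self._single_tubule(), ImagingSpec(shot_noise=False))
        # mask row extent at the tubule centre ~ width / pixel_size
        col = int(2.5 / (16.23 / 1000.0))
        extent = mask[:, col].sum()
        assert extent == pytest.approx(250.0 / 16.23, abs=2)


class TestTransients:
    def test_noiseless_decay_log_linear(self):
        spec = TransientSpec(k_syst=1.0, k_caff=0.5, noise_sd=0.0)
        data = generate_transients(spec)
        t, y = data["time_s"], data["systolic"]
        t_peak = data["truth"]["peak_time_systolic_s"]
        sel = t >= t_peak + 0.01
        logy = np.log(y[sel] - spec.baseline)
        slope = np.polyfit(t[sel], logy, 1)[0]
        assert slope == pytest.approx(-1.0, abs=1e-6)

    def test_equal_rates_identical_decays(self):
        # with k_syst == k_caff the two decays are the same curve relative to
        # their respective peaks
        spec = TransientSpec(k_syst=0.8, k_caff=0.8, noise_sd=0.0)
        data = generate_transients(spec)
        t = data["time_s"]
        i_s = np.searchsorted(t, data["truth"]["peak_time_systolic_s"])
        i_c = np.searchsorted(t, data["truth"]["peak_time_caffeine_s"])
        n = min(t.size - i_s, t.size - i_c)
        assert np.allclose(data["systolic"][i_s:i_s + n],
                           data["caffeine"][i_c:i_c + n])

    def test_short_duration_flags_fit_window(self):
        spec = TransientSpec(k_caff=0.68, k_syst=2.0, duration=3.0)
        assert generate_transients(spec)["truth"]["fit_window_too_short"]
        long = TransientSpec(k_caff=0.68, k_syst=2.0, duration=8.0)
        assert not generate_transients(long)["truth"]["fit_window_too_short"]

    def test_rate_ordering_enforced(self):
        with pytest.raises(ValueError, match="k_syst >= k_caff"):
            TransientSpec(k_syst=0.5, k_caff=0.8).validate()

    def test_caffeine_rate_roundtrips_through_monoexp_fit(self):
        # decay rate in the atrial caffeine-transient regime recovers within
        # 3% at SNR 20 (median over 100 seeds)
        from tatnet import calcium
        errs = []
        for seed in range(100):
            spec = TransientSpec(k_syst=2.0, k_caff=0.68, noise_sd=1.5 / 20.0,
                                 seed=seed)
            data = generate_transients(spec)
            fit = calcium.fit_monoexp(
                calcium.Trace(data["time_s"], data["caffeine"], kind="caffeine"))
            errs.append((fit.k - 0.68) / 0.68)
        assert abs(np.median(errs)) < 0.03


class TestAPTrace:
    def test_threshold_crossing_matches_direct_scan(self):
        data = generate_ap_trace(APTraceSpec(noise_sd=0.0))
        t, y = data["time_ms"], data["dff"]
        idx = np.nonzero(y > 0.04)[0][0]
        analytic = data["truth"]["threshold_crossing_delay_ms"] + data["stim_end_ms"]
        assert t[idx] == pytest.approx(analytic, abs=data["time_ms"][1])

    def test_zero_amplitude_flags_no_ap(self):
        data = generate_ap_trace(APTraceSpec(amplitude=0.0))
        assert data["truth"]["no_ap"]
        assert np.all(data["dff"] == 0.0)
        assert data["truth"]["threshold_crossing_delay_ms"] is None

    def test_max_slope_is_amplitude_over_tau(self):
        spec = APTraceSpec(sample_interval=0.01, noise_sd=0.0)
        data = generate_ap_trace(spec)
        slope = np.max(np.diff(data["dff"])) / spec.sample_interval
        analytic = spec.amplitude / spec.upstroke_tau
        assert slope == pytest.approx(analytic, rel=0.01)
        assert data["truth"]["max_slope_per_ms"] == pytest.approx(analytic)

    def test_trace_flat_before_onset(self):
        data = generate_ap_trace(APTraceSpec(noise_sd=0.0))
        before = data["time_ms"] < data["truth"]["onset_time_ms"]
        assert np.all(data["dff"][before] == 0.0)


class TestSegmentSetRoundTrip:
    def test_json_round_trip(self, small_network_spec):
        segs = generate_network_geometry(small_network_spec, seed=1)
        back = simulate.SegmentSet.from_json(segs.to_json())
        assert back.truth == segs.truth
        assert len(back.segments) == len(segs.segments)
        assert dataclasses.asdict(back.segments[0]) == dataclasses.asdict(segs.segments[0])
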