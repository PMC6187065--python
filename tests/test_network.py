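"""Skeleton graph construction, network metrics and component classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import line_pixels, pixels_to_mask
from tatnet import network
from tatnet.network import (
    Skeleton,
    build_graph,
    classify_components,
    network_metrics,
    orientation_histogram,
    skeletonize,
)

from _oracles import skeleton_graph_oracle

PS = 16.23  # nm


def skel_from_pixels(pixels, shape=None):
    if shape is None:
        shape = (max(p[0] for p in pixels) + 3, max(p[1] for p in pixels) + 3)
    return Skeleton(pixels=set(pixels), pixel_size=PS, shape=shape)


class TestSkeletonize:
    def test_one_pixel_line_is_fixed_point(self):
        pixels = {(5, c) for c in range(3, 20)}
        mask = pixels_to_mask(pixels)
        skel = skeletonize(mask, PS)
        assert skel.pixels == pixels

    def test_wide_bar_reduces_to_centerline(self):
        mask = np.zeros((20, 60), bool)
        mask[8:13, 5:55] = True  # 5 px wide bar
        skel = skeletonize(mask, PS)
        rows = {r for r, _ in skel.pixels}
        assert rows <= {9, 10, 11}  # within one pixel of the central row
        # one pixel per column: a 1-px-thin centerline
        cols = [c for _, c in skel.pixels]
        assert len(cols) == len(set(cols))
        # thinning erodes the bar ends by about its half-width; the tip
        # extension restores them, giving the bar length within ~1 px
        graph = build_graph(skel, prune_spurs_px=0)
        corrected = graph.total_length_um + network.measure_tip_extension(mask, graph)
        assert corrected == pytest.approx(49 * PS / 1000.0, abs=1.5 * PS / 1000.0)

    def test_empty_mask_gives_empty_skeleton(self):
        skel = skeletonize(np.zeros((10, 10), bool), PS)
        assert skel.pixels == set()

    def test_plus_sign_yields_single_junction(self):
        mask = np.zeros((21, 21), bool)
        mask[10, 2:19] = True
        mask[2:19, 10] = True
        skel = skeletonize(mask, PS)
        graph = build_graph(skel, prune_spurs_px=0)
        assert graph.n_junctions == 1
        assert graph.n_branches == 4


class TestBuildGraph:
    def test_straight_line_branch_length(self):
        skel = skel_from_pixels({(5, c) for c in range(100)})
        graph = build_graph(skel, prune_spurs_px=0)
        assert graph.n_junctions == 0
        assert len(graph.endpoints) == 2
        assert graph.n_branches == 1
        assert graph.total_length_um == pytest.approx(99 * PS / 1000.0)

    def test_isolated_pixel_is_degenerate(self):
        skel = skel_from_pixels({(4, 4)})
        graph = build_graph(skel, prune_spurs_px=0)
        assert graph.isolated == [(4, 4)]
        assert graph.n_branches == 0
        assert graph.total_length_um == 0.0

    def test_plus_sign_graph(self):
        pixels = {(10, c) for c in range(5, 16)} | {(r, 10) for r in range(5, 16)}
        graph = build_graph(skel_from_pixels(pixels), prune_spurs_px=0)
        assert graph.n_junctions == 1
        assert graph.n_branches == 4
        assert len(graph.endpoints) == 4

    def test_closed_loop_is_single_self_branch(self):
        # diamond ring: every pixel has exactly two (diagonal) neighbours
        pixels = {(10 + dr, 10 + dc) for dr in range(-6, 7) for dc in range(-6, 7)
                  if abs(dr) + abs(dc) == 6}
        graph = build_graph(skel_from_pixels(pixels), prune_spurs_px=0)
        assert graph.n_junctions == 0
        assert graph.n_branches == 1
        assert graph.total_length_um == pytest.approx(
            len(pixels) * math.sqrt(2.0) * PS / 1000.0)

    def test_spur_pruning_removes_short_terminal_branch(self):
        pixels = {(10, c) for c in range(40)} | {(9, 20), (8, 20)}
        raw = build_graph(skel_from_pixels(pixels), prune_spurs_px=0)
        pruned = build_graph(skel_from_pixels(pixels), prune_spurs_px=4)
        assert raw.n_junctions == 1
        assert pruned.n_junctions == 0
        assert pruned.n_branches == 1

    @pytest.mark.parametrize("fixture", ["line", "L", "plus", "grid"])
    def test_hand_fixtures_match_oracle(self, fixture):
        if fixture == "line":
            pixels = {(3, c) for c in range(1, 30)}
        elif fixture == "L":
            pixels = {(3, c) for c in range(1, 20)} | {(r, 19) for r in range(3, 15)}
        elif fixture == "plus":
            pixels = {(10, c) for c in range(1, 20)} | {(r, 10) for r in range(1, 20)}
        else:  # grid of crossing lines
            pixels = set()
            for r in (5, 15, 25):
                pixels |= {(r, c) for c in range(2, 30)}
            for c in (8, 18, 28):
                pixels |= {(r, c) for r in range(2, 28)}
        graph = build_graph(skel_from_pixels(pixels), prune_spurs_px=0)
        oracle = skeleton_graph_oracle(pixels, PS)
        assert graph.n_junctions == oracle["n_junctions"]
        assert graph.n_branches == oracle["n_branches"]
        assert graph.total_length_um == pytest.approx(oracle["total_length_um"])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_random_skeletons_match_oracle(self, data):
        """Graph statistics equal exhaustive enumeration on small random masks."""
        shape = (data.draw(st.integers(6, 32)), data.draw(st.integers(6, 32)))
        density = data.draw(st.floats(0.1, 0.5))
        seed = data.draw(st.integers(0, 10**6))
        rng = np.random.default_rng(seed)
        mask = rng.random(shape) < density
        skel = skeletonize(mask, PS)
        graph = build_graph(skel, prune_spurs_px=0)
        oracle = skeleton_graph_oracle(skel.pixels, PS)
        assert graph.n_junctions == oracle["n_junctions"]
        assert graph.n_branches == oracle["n_branches"]
        assert graph.total_length_um == pytest.approx(oracle["total_length_um"])


class TestNetworkMetrics:
    def test_line_density_arithmetic(self):
        skel = skel_from_pixels({(5, c) for c in range(100)})
        graph = build_graph(skel, prune_spurs_px=0)
        m = network_metrics(graph, roi_area=100.0)
        assert m.density == pytest.approx(99 * PS / 1000.0 / 100.0)
        assert m.junction_density == 0.0

    def test_doubling_area_halves_densities(self):
        pixels = {(10, c) for c in range(1, 20)} | {(r, 10) for r in range(1, 20)}
        graph = build_graph(skel_from_pixels(pixels), prune_spurs_px=0)
        m1 = network_metrics(graph, roi_area=50.0)
        m2 = network_metrics(graph, roi_area=100.0)
        assert m2.density == pytest.approx(m1.density / 2.0)
        assert m2.junction_density == pytest.approx(m1.junction_density / 2.0)

    def test_zero_area_raises(self):
        graph = build_graph(skel_from_pixels({(1, 1)}), prune_spurs_px=0)
        with pytest.raises(ValueError, match="roi_area"):
            network_metrics(graph, roi_area=0.0)

    def test_junction_merging_counts_near_pairs_once(self):
        # two plus-signs 4 px apart: 2 raw junctions, 1 merged at 0.5 μm radius
        pixels = ({(10, c) for c in range(1, 30)}
                  | {(r, 10) for r in range(1, 20)} | {(r, 14) for r in range(1, 20)})
        graph = build_graph(skel_from_pixels(pixels), prune_spurs_px=0)
        assert graph.n_junctions == 2
        merged = network_metrics(graph, roi_area=10.0, junction_merge_radius_um=0.5)
        assert merged.n_junctions == 1


class TestOrientation:
    @pytest.mark.parametrize("angle", [0.0, 45.0, 90.0, -45.0, 30.0])
    def test_single_line_weight_in_correct_bin(self, angle):
        skel = skel_from_pixels(line_pixels(angle, n=150), shape=(300, 300))
        hist = orientation_histogram(skel, reference_angle=0.0)
        centers = hist.bin_centers
        peak = centers[np.argmax(hist.weights)]
        # fold 90/-90 equivalence
        diff = abs((peak - angle + 90.0) % 180.0 - 90.0)
        assert diff <= 5.0  # within one bin of the true orientation

    def test_mixture_mass_ratio(self):
        pix = line_pixels(0.0, n=140, start=(10, 10)) | line_pixels(
            90.0, n=60, start=(20, 200))
        skel = skel_from_pixels(pix, shape=(300, 300))
        hist = orientation_histogram(skel, reference_angle=0.0)
        centers = np.abs(hist.bin_centers)
        near_at = centers <= 22.5
        near_tt = centers > 67.5
        mass_at = hist.weights[near_at].sum()
        mass_tt = hist.weights[near_tt].sum()
        ratio = mass_at / (mass_at + mass_tt)
        assert ratio == pytest.approx(140.0 / 200.0, abs=0.03)

    def test_histogram_mass_equals_skeleton_length(self):
        pix = line_pixels(30.0, n=100) | line_pixels(75.0, n=50, start=(20, 150))
        skel = skel_from_pixels(pix, shape=(300, 300))
        hist = orientation_histogram(skel, reference_angle=12.0)
        graph = build_graph(skel, prune_spurs_px=2.0)
        assert hist.total_length_um == pytest.approx(graph.total_length_um, rel=1e-9)

    def test_empty_skeleton_raises(self):
        skel = Skeleton(pixels=set(), pixel_size=PS, shape=(5, 5))
        with pytest.raises(ValueError, match="empty skeleton"):
            orientation_histogram(skel, 0.0)

    def test_reference_angle_shifts_histogram(self):
        skel = skel_from_pixels(line_pixels(45.0, n=150), shape=(300, 300))
        h0 = orientation_histogram(skel, reference_angle=0.0)
        h45 = orientation_histogram(skel, reference_angle=45.0)
        assert abs(h0.bin_centers[np.argmax(h0.weights)] - 45.0) <= 5.0
        assert abs(h45.bin_centers[np.argmax(h45.weights)]) <= 5.0


class TestClassification:
    def _summary_for_line(self, angle, reference=0.0, window=22.5):
        skel = skel_from_pixels(line_pixels(angle, n=150), shape=(300, 300))
        hist = orientation_histogram(skel, reference_angle=reference)
        return classify_components(hist, roi_area=100.0, window=window)

    def test_pure_axial(self):
        s = self._summary_for_line(0.0)
        assert s.relative_fraction["AT"] == pytest.approx(1.0)
        assert s.relative_fraction["OT"] == 0.0
        assert s.relative_fraction["TT"] == 0.0

    def test_pure_transverse(self):
        s = self._summary_for_line(90.0)
        assert s.relative_fraction["TT"] == pytest.approx(1.0)

    def test_oblique_either_sign(self):
        for angle in (45.0, -45.0):
            s = self._summary_for_line(angle)
            assert s.relative_fraction["OT"] == pytest.approx(1.0, abs=0.05)

    def test_conservation_classified_plus_unclassified(self):
        skel = skel_from_pixels(
            line_pixels(10.0, n=100) | line_pixels(80.0, n=70, start=(30, 150)),
            shape=(300, 300))
        hist = orientation_histogram(skel, reference_angle=0.0)
        s = classify_components(hist, roi_area=50.0, window=5.0)
        classified_density = sum(s.absolute_density.values())
        assert classified_density + s.unclassified_fraction * s.total_density == \
            pytest.approx(s.total_density, rel=1e-9)

    def test_strict_window_leaves_mass_unclassified(self):
        s = self._summary_for_line(20.0, window=5.0)
        assert s.unclassified_fraction > 0.5

    def test_rotation_equivariance_quarter_turn(self):
        pix = line_pixels(30.0, n=120, start=(20, 20))
        skel = skel_from_pixels(pix, shape=(200, 200))
        hist = orientation_histogram(skel, reference_angle=0.0)
        s0 = classify_components(hist, roi_area=100.0)
        # rotate pixels by 90° (r, c) -> (c, N-1-r) and the reference with them
        rot = {(c, 200 - 1 - r) for r, c in pix}
        skel90 = skel_from_pixels(rot, shape=(200, 200))
        h90 = orientation_histogram(skel90, reference_angle=90.0)
        s90 = classify_components(h90, roi_area=100.0)
        for k in ("AT", "OT", "TT"):
            assert s90.relative_fraction[k] == pytest.approx(
                s0.relative_fraction[k], abs=0.06)


class TestDensityPixelSizeInvariance:
    def test_same_geometry_two_pixel_sizes(self, small_network_spec):
        """Physical density agrees between fine and coarse rasterisation."""
        from tatnet import pipeline, prep, simulate
        segs = simulate.generate_network_geometry(small_network_spec, seed=4)
        results = []
        for ps in (40.0, 114.0):
            imaging = simulate.ImagingSpec(pixel_size=ps, psf_fwhm=0.0,
                                           shot_noise=False, read_noise_sd=0.0)
            img, _ = simulate.render_image(segs, imaging)
            roi = pipeline._roi_from_polygon(segs, img.shape, ps)
            res = pipeline.analyze_network_image(
                img, roi,
                prep.PreprocessParams(exclude_margin=0.0, background_radius=0.0,
                                      smooth_sigma=0.0, threshold_mode="fixed",
                                      fixed_threshold=90.0),
                pixel_size=ps)
            results.append(res["metrics"].density)
        assert results[0] == pytest.approx(results[1], rel=0.05)
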