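import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gestaltmask.em_mask import (
    EMConfig,
    OrientationHistogram,
    entropy_upper_bound,
    gestalt_likelihood,
    nongestalt_likelihood,
    objective_term,
    objective_value,
    orientation_histogram,
    principal_direction,
    rasterize_mask,
    run_em,
    shannon_entropy,
    update_length,
    update_width,
)
from gestaltmask.errors import ConfigurationError
from gestaltmask.synthetic import feature_maps_from_field, fig6_fixture, line_scene


def hist_from_heights(heights, target_bin, n=18):
    heights = np.asarray(heights, dtype=float)
    return OrientationHistogram(heights=heights, n_samples=n, target_bin=target_bin)


class TestEntropy:
    def test_upper_bound_values(self):
        assert entropy_upper_bound(1) == 0.0
        assert entropy_upper_bound(49) == pytest.approx(math.log(49))
        with pytest.raises(ConfigurationError):
            entropy_upper_bound(0)

    def test_single_occupied_bin_has_zero_entropy(self):
        h = np.zeros(49)
        h[3] = 1.0
        assert shannon_entropy(hist_from_heights(h, 3)) == 0.0

    def test_uniform_heights_attain_the_bound(self):
        h = np.full(49, 1 / 49)
        assert shannon_entropy(hist_from_heights(h, 0)) == pytest.approx(math.log(49))

    def test_fifteen_three_split(self):
        h = np.zeros(49)
        h[0], h[1] = 15 / 18, 3 / 18
        assert shannon_entropy(hist_from_heights(h, 1)) == pytest.approx(0.45056, abs=1e-4)

    def test_entropy_bounded_on_random_histograms(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            counts = rng.multinomial(30, np.full(49, 1 / 49))
            h = counts / counts.sum()
            H = shannon_entropy(hist_from_heights(h, 0, 30))
            assert 0.0 <= H <= entropy_upper_bound(49) + 1e-12


class TestRasterize:
    def test_axis_aligned_default_square(self):
        fp = rasterize_mask((10, 10), 7, 7, 0.0, (31, 31))
        assert len(fp) == 49
        assert fp[:, 0].min() == 7 and fp[:, 0].max() == 13

    def test_phi_90_swaps_axes(self):
        a = rasterize_mask((15, 15), 11, 3, 0.0, (31, 31))
        b = rasterize_mask((15, 15), 11, 3, 90.0, (31, 31))
        swapped = {(c, r) for r, c in map(tuple, b)}
        assert swapped == set(map(tuple, a))

    def test_corner_clipping(self):
        fp = rasterize_mask((0, 0), 7, 7, 0.0, (64, 64))
        assert len(fp) == 16  # 4x4 surviving quadrant

    def test_target_always_included(self):
        fp = rasterize_mask((5, 5), 1, 1, 37.0, (11, 11))
        assert (5, 5) in set(map(tuple, fp))


class TestHistogram:
    def test_single_angle_single_bin(self):
        theta = np.full((5, 5), 30.0)
        fp = np.array([(r, c) for r in range(5) for c in range(5)])
        hist = orientation_histogram(theta, fp, 49, 30.0)
        assert hist.h_max == 1.0
        assert hist.h_T == 1.0
        assert hist.heights.sum() == pytest.approx(1.0)

    def test_fig6b_fifteen_three_bookkeeping(self):
        theta, fp, target, bn = fig6_fixture("b")
        hist = orientation_histogram(theta, fp, bn, theta[target])
        assert hist.n_samples == 18
        assert hist.h_max == pytest.approx(15 / 18)
        assert hist.h_T == pytest.approx(3 / 18)

    def test_all_null_footprint(self):
        theta = np.full((5, 5), np.nan)
        fp = np.array([(0, 0), (1, 1)])
        hist = orientation_histogram(theta, fp, 49, np.nan)
        assert hist.n_samples == 0
        assert np.all(hist.heights == 0)
        assert hist.target_bin is None


class TestLikelihoods:
    def test_uniform_gestalt_is_exactly_zero(self):
        theta, fp, target, bn = fig6_fixture("a")
        hist = orientation_histogram(theta, fp, bn, theta[target])
        assert gestalt_likelihood(hist, bn) == 0.0

    def test_single_bin_gestalt_is_exactly_one(self):
        theta, fp, target, bn = fig6_fixture("d")
        hist = orientation_histogram(theta, fp, bn, theta[target])
        assert gestalt_likelihood(hist, bn) == 1.0

    def test_majority_target_worked_example(self):
        theta, fp, target, bn = fig6_fixture("c")
        hist = orientation_histogram(theta, fp, bn, theta[target])
        assert hist.h_T / hist.h_max == pytest.approx(1.0)
        assert gestalt_likelihood(hist, bn) == pytest.approx(0.885, abs=0.01)

    def test_minority_target_worked_example(self):
        theta, fp, target, bn = fig6_fixture("b")
        hist = orientation_histogram(theta, fp, bn, theta[target])
        assert hist.h_T / hist.h_max == pytest.approx(0.2)
        assert gestalt_likelihood(hist, bn) == pytest.approx(0.178, abs=0.01)

    def test_nongestalt_degenerate_cases(self):
        h = np.zeros(49)
        h[2] = 1.0
        assert nongestalt_likelihood(hist_from_heights(h, 2), 49) == 0.0  # zero entropy
        assert nongestalt_likelihood(hist_from_heights(h, 5), 49) == 0.0  # empty target bin

    def test_nongestalt_uniform_occupied_target_is_one(self):
        h = np.full(49, 1 / 49)
        assert nongestalt_likelihood(hist_from_heights(h, 7, 49), 49) == pytest.approx(1.0)

    def test_likelihood_range_on_random_histograms(self):
        rng = np.random.default_rng(5)
        for _ in range(10_000):
            bn = int(rng.integers(2, 50))
            counts = rng.multinomial(int(rng.integers(1, 60)), np.full(bn, 1 / bn))
            h = counts / counts.sum()
            hist = hist_from_heights(h, int(rng.integers(0, bn)), counts.sum())
            assert 0.0 <= gestalt_likelihood(hist, bn) <= 1.0
            assert 0.0 <= nongestalt_likelihood(hist, bn) <= 1.0


class TestUpdates:
    def test_width_floor_when_likelihood_rises(self):
        assert update_width(0.8, 0.5, 7) == 1  # floor(1.4) = 1
        assert update_width(0.3, 0.5, 7) == 5  # ceil(4.9)
        assert update_width(0.95, 0.0, 7) == 1  # clamp branch

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(st.floats(0, 1), st.floats(0, 1), st.integers(2, 12))
    def test_width_always_within_bounds(self, p_t, p_prev, init):
        r = math.sqrt(init * init)
        w = update_width(p_t, p_prev, r)
        assert 1 <= w <= math.ceil(r)
        L = update_length(init * init, w)
        assert L * w == init * init

    def test_length_examples(self):
        assert update_length(49, 7) == 7
        assert update_length(49, 2) == 24.5
        assert update_length(49, 1) == 49


class TestPrincipalDirection:
    def test_single_bin_center_with_5_degree_bins(self):
        h = np.zeros(36)
        h[26] = 1.0  # bin [40, 45)
        hist = hist_from_heights(h, 26, 10)
        assert principal_direction(hist) == pytest.approx(42.5)

    def test_tie_breaks_toward_previous_direction(self):
        h = np.zeros(36)
        h[0] = h[26] = 0.5
        hist = hist_from_heights(h, 0, 10)
        assert principal_direction(hist, prev_phi=40.0) == pytest.approx(42.5)
        assert principal_direction(hist, prev_phi=-85.0) == pytest.approx(-87.5)
        assert principal_direction(hist) == pytest.approx(-87.5)  # lowest index

    def test_empty_histogram_has_no_direction(self):
        hist = hist_from_heights(np.zeros(36), None, 0)
        assert principal_direction(hist) is None


class TestObjective:
    def test_zero_residual_at_fixed_point(self):
        assert objective_term(7 * (1 - 0.3), 0.3, 7) == 0.0

    def test_unit_residual_example(self):
        assert objective_term(1, 1.0, 7) == 1.0

    def test_mean_over_candidates(self):
        assert objective_value([1.0, 3.0], 4) == 1.0


class TestRunEM:
    def test_planted_line_on_random_complement_background(self):
        maps, target = line_scene(45.0, background="random", seed=1)
        cm = run_em(target, maps, EMConfig())
        assert cm.converged
        assert cm.state.W == 1
        assert cm.p_c > 0.5
        assert abs(cm.state.phi - 45.0) <= 180 / 49

    def test_isotropic_field_yields_low_likelihood_and_wide_mask(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            maps = feature_maps_from_field(rng.uniform(-90, 90, (41, 41)))
            cm = run_em((20, 20), maps, EMConfig())
            assert cm.p_c < 0.2

    def test_uniform_orientation_field_converges_immediately_to_p_one(self):
        maps = feature_maps_from_field(np.full((21, 21), 10.0))
        cm = run_em((10, 10), maps, EMConfig())
        assert cm.converged
        assert cm.p_c == 1.0
        assert cm.state.W == 1

    def test_null_target_returns_degenerate_flag(self):
        theta = np.full((15, 15), np.nan)
        maps = feature_maps_from_field(theta)
        cm = run_em((7, 7), maps, EMConfig())
        assert cm.degenerate_target
        assert cm.p_c == 0.0 and cm.p_bar_c == 0.0

    def test_receptive_field_enlarges_beyond_initial_square(self):
        maps, target = line_scene(45.0, background="constant", seed=0)
        cm = run_em(target, maps, EMConfig())
        # sampling geometries: the initial square plus each post-update state
        geometries = [(7.0, 7, 0.0)] + [(s.L, s.W, s.phi) for s in cm.trace]
        union = set()
        for L, W, phi in geometries:
            fp = rasterize_mask(target, L, W, phi, maps.shape)
            union |= set(map(tuple, fp))
        assert len(union) > 49

    def test_descent_and_bounds_on_random_traces(self, random_field_traces):
        for cm in random_field_traces:
            for step in cm.trace:
                assert step.delta_e <= 1e-12
                assert 1 <= step.W <= 7
                assert 7 <= step.L <= 49
                assert step.L * step.W == pytest.approx(49)

    def test_out_of_bounds_target_raises(self):
        maps = feature_maps_from_field(np.zeros((9, 9)))
        with pytest.raises(ConfigurationError):
            run_em((20, 3), maps, EMConfig())
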