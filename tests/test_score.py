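import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from depthcnv import (
    DepthSegment,
    GaussianComponent,
    HalfGridMixture,
    fit_constrained_mixture,
    round_to_half,
    score_segment,
    score_segments,
    segment_window,
)

from _oracles import normal_upper_tail


def seg(depth, start=1, end=100, n=50):
    return DepthSegment("s", "1", start, end, n, depth)


class TestRoundToHalf:
    @pytest.mark.parametrize(
        "x,expected",
        [
            (0.98, 1.0),
            (0.51, 0.5),
            (0.72, 0.5),   # |0.22| < |0.28|
            (0.78, 1.0),
            (0.0, 0.0),
            (1.6, 1.5),
            # exact quarter-point ties resolve toward the diploid state
            (0.75, 1.0),
            (1.25, 1.0),
            (0.25, 0.5),
            (1.75, 1.5),  # tie between 1.5 and 2.0: 1.5 is nearer diploid
        ],
    )
    def test_nearest_with_diploid_ties(self, x, expected):
        assert round_to_half(x) == expected

    @given(st.floats(0.0, 5.0))
    @settings(max_examples=100, deadline=None)
    def test_result_on_grid_and_within_quarter(self, x):
        r = round_to_half(x)
        assert (r * 2) == int(r * 2)
        assert abs(x - r) <= 0.25 + 1e-12


class TestMixture:
    def test_grid_spans_observed_range(self):
        grid = HalfGridMixture.grid_for_range(0.4, 1.6)
        np.testing.assert_array_equal(grid, [0.5, 1.0, 1.5])

    def test_two_component_recovery(self):
        rng = np.random.default_rng(5)
        x = np.concatenate(
            [rng.normal(1.0, 0.05, 700), rng.normal(0.5, 0.05, 300)]
        )
        comps = {c.ideal_depth: c for c in fit_constrained_mixture(x)}
        assert abs(comps[1.0].weight - 0.7) < 0.05
        assert abs(comps[0.5].weight - 0.3) < 0.05
        assert abs(comps[1.0].sd - 0.05) / 0.05 < 0.3
        assert abs(comps[0.5].sd - 0.05) / 0.05 < 0.3

    def test_three_component_recovery(self):
        rng = np.random.default_rng(9)
        x = np.concatenate(
            [
                rng.normal(0.5, 0.04, 200),
                rng.normal(1.0, 0.06, 600),
                rng.normal(1.5, 0.04, 200),
            ]
        )
        comps = {c.ideal_depth: c for c in fit_constrained_mixture(x)}
        for mean, w, sd in [(0.5, 0.2, 0.04), (1.0, 0.6, 0.06), (1.5, 0.2, 0.04)]:
            assert abs(comps[mean].weight - w) < 0.05
            assert abs(comps[mean].sd - sd) / sd < 0.3

    def test_all_identical_degenerate(self):
        comps = fit_constrained_mixture(np.full(50, 1.0))
        assert len(comps) == 1
        assert comps[0].ideal_depth == 1.0
        assert comps[0].weight == pytest.approx(1.0)
        assert comps[0].sd == pytest.approx(0.01)  # floored, never singular

    def test_weights_sum_to_one_and_components_retained(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(1.0, 0.05, 500), [0.02, 1.98]])
        comps = fit_constrained_mixture(x)
        assert [c.ideal_depth for c in comps] == [0.0, 0.5, 1.0, 1.5, 2.0]
        assert abs(sum(c.weight for c in comps) - 1.0) < 1e-6
        assert all(c.sd > 0 for c in comps)

    def test_log_likelihood_non_decreasing(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(1.0, 0.08, 300), rng.normal(0.5, 0.08, 100)])
        mix = HalfGridMixture().fit(x)
        lls = np.array(mix.log_likelihoods_)
        assert np.all(np.diff(lls) >= -1e-7)

    def test_window_range_widens_grid(self):
        comps = fit_constrained_mixture(
            np.full(10, 1.0), window_range=(0.5, 1.5)
        )
        assert [c.ideal_depth for c in comps] == [0.5, 1.0, 1.5]


class TestScoreSegment:
    def test_score_one_at_component_mean(self):
        comps = [GaussianComponent(1.0, 0.05, 1.0)]
        sc = score_segment(seg(1.0), comps)
        assert sc.score == pytest.approx(1.0)
        assert sc.ideal_depth == 1.0
        assert sc.is_hq

    def test_closed_form_against_independent_tail(self):
        comps = [GaussianComponent(0.5, 0.07, 0.4), GaussianComponent(1.0, 0.05, 0.6)]
        for depth in [0.47, 0.62, 0.9, 1.04, 1.21]:
            sc = score_segment(seg(depth), comps)
            ideal = round_to_half(depth)
            sd = {0.5: 0.07, 1.0: 0.05}[ideal]
            expected = 2.0 * normal_upper_tail(abs(depth - ideal) / sd)
            assert sc.score == pytest.approx(expected, rel=1e-10)

    def test_hq_boundary_is_strict(self):
        sd = 0.05
        comps = [GaussianComponent(1.0, sd, 1.0)]
        sc = score_segment(seg(1.0 + 1.6449 * sd), comps)
        assert sc.score == pytest.approx(0.1, abs=5e-4)
        assert not sc.is_hq  # s > 0.1 strictly required
        hq = score_segment(seg(1.0 + 1.60 * sd), comps)
        assert hq.is_hq

    def test_nearest_multiple_assignment(self):
        comps = [GaussianComponent(0.5, 0.1, 0.5), GaussianComponent(1.0, 0.1, 0.5)]
        assert score_segment(seg(0.72), comps).ideal_depth == 0.5

    @given(st.floats(0.0, 0.24), st.floats(0.0, 0.24))
    @settings(max_examples=60, deadline=None)
    def test_score_monotone_in_deviation(self, d1, d2):
        comps = [GaussianComponent(1.0, 0.05, 1.0)]
        s1 = score_segment(seg(1.0 + d1), comps).score
        s2 = score_segment(seg(1.0 + d2), comps).score
        if d1 < d2:
            assert s1 >= s2
        assert 0 < s1 <= 1.0


def test_hq_segments_cluster_at_half_integers(small_rdm):
    """On a clean simulated cohort, fitted segments land near 0.5 multiples."""
    segments = segment_window(small_rdm)
    comps = fit_constrained_mixture([s.fitted_depth for s in segments])
    scored = score_segments(segments, comps)
    hq = [s for s in scored if s.is_hq]
    assert hq
    near = [
        s for s in hq if abs(s.segment.fitted_depth - s.ideal_depth) <= 0.15
    ]
    assert len(near) / len(hq) >= 0.95
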