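import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from depthcnv import (
    PiecewiseConstantRegressor,
    SegmentationParams,
    fit_piecewise_constant,
    segment_window,
)

from _oracles import naive_greedy_cuts, optimal_cuts_dp, sse


def cuts_of(segments, positions):
    """Interior cut marker-indices implied by a segment list."""
    pos = list(positions)
    return [pos.index(s.start_bp) for s in segments[1:]]


class TestFitPiecewiseConstant:
    def test_noiseless_constant_single_segment(self):
        pos = np.arange(1, 301)
        segs = fit_piecewise_constant(pos, np.ones(300))
        assert len(segs) == 1
        assert segs[0].fitted_depth == 1.0
        assert (segs[0].start_bp, segs[0].end_bp, segs[0].n_markers) == (1, 300, 300)

    def test_clean_step_two_segments_at_true_boundary(self):
        pos = np.arange(1, 301)
        y = np.concatenate([np.full(200, 1.0), np.full(100, 0.5)])
        segs = fit_piecewise_constant(pos, y)
        assert len(segs) == 2
        assert (segs[0].end_bp, segs[1].start_bp) == (200, 201)
        assert (segs[0].fitted_depth, segs[1].fitted_depth) == (1.0, 0.5)
        # exhaustive single-split check: no other cut does better
        best = min(
            range(6, 295), key=lambda i: sse(y[:i]) + sse(y[i:])
        )
        assert best == 200

    def test_min_leaf_constrains_cut_placement(self):
        # 10 markers at 1.0 then 5 at 0.0: the true boundary (10/5) is
        # forbidden by min_leaf=6, so the cut shifts left to 9/6 — the same
        # behaviour as rpart with minbucket=6
        y = np.concatenate([np.full(10, 1.0), np.full(5, 0.0)])
        segs = fit_piecewise_constant(np.arange(1, 16), y, SegmentationParams(min_leaf=6))
        assert [s.n_markers for s in segs] == [9, 6]
        assert all(s.n_markers >= 6 for s in segs)

    def test_min_leaf_forbids_any_split_when_too_few_markers(self):
        y = np.concatenate([np.full(6, 1.0), np.full(5, 0.0)])
        segs = fit_piecewise_constant(np.arange(1, 12), y, SegmentationParams(min_leaf=6))
        assert len(segs) == 1  # 11 < 2 * min_leaf: node is never split

    def test_fitted_depth_is_member_mean(self, small_rdm):
        col = small_rdm.rel_depth[:, 0]
        keep = ~np.isnan(col)
        pos, y = small_rdm.positions[keep], col[keep]
        segs = fit_piecewise_constant(pos, y)
        for s in segs:
            member = y[(pos >= s.start_bp) & (pos <= s.end_bp)]
            assert len(member) == s.n_markers
            assert abs(member.mean() - s.fitted_depth) < 1e-9

    def test_errors(self):
        with pytest.raises(ValueError):
            fit_piecewise_constant([], [])
        with pytest.raises(ValueError, match="NaN"):
            fit_piecewise_constant([1, 2, 3], [1.0, np.nan, 1.0])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_naive_greedy_oracle_on_noise(self, seed):
        """Fast cumsum splitter == transparent O(n^2) greedy on noisy steps."""
        rng = np.random.default_rng(seed)
        levels = rng.choice([0.0, 0.5, 1.0, 1.5], size=4)
        lens = rng.integers(8, 60, 4)
        y = np.concatenate([np.full(n, lv) for n, lv in zip(lens, levels)])
        y = y + rng.normal(0, 0.08, len(y))
        pos = np.arange(1, len(y) + 1)
        segs = fit_piecewise_constant(pos, y)
        assert cuts_of(segs, pos) == naive_greedy_cuts(y, 0.01, 6)

    @pytest.mark.parametrize("pieces", [
        [(40, 1.0), (30, 0.5), (50, 1.0)],
        [(20, 1.0), (25, 0.0), (20, 1.0), (30, 1.5)],
        [(100, 1.0), (100, 0.5)],
    ])
    def test_exact_recovery_matches_dp_oracle(self, pieces):
        """Noiseless step functions: greedy cuts == true cuts == DP-optimal."""
        y = np.concatenate([np.full(n, lv) for n, lv in pieces])
        pos = np.arange(1, len(y) + 1)
        segs = fit_piecewise_constant(pos, y)
        true_cuts = list(np.cumsum([n for n, _ in pieces])[:-1])
        assert cuts_of(segs, pos) == true_cuts
        assert optimal_cuts_dp(y, len(pieces), 6) == true_cuts

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_piecewise_sse_never_worse_than_constant(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(12, 120))
        y = rng.normal(1.0, 0.3, n) + rng.choice([0.0, -0.5], n)
        pos = np.arange(1, n + 1)
        reg = PiecewiseConstantRegressor().fit(pos, y)
        fitted_sse = float(((y - reg.predict(pos)) ** 2).sum())
        assert fitted_sse <= sse(y) + 1e-9

    def test_lower_complexity_never_fewer_segments(self):
        rng = np.random.default_rng(11)
        y = np.concatenate(
            [np.full(60, 1.0), np.full(40, 0.5), np.full(60, 1.0), np.full(40, 1.5)]
        ) + rng.normal(0, 0.1, 200)
        pos = np.arange(1, 201)
        counts = [
            len(fit_piecewise_constant(pos, y, SegmentationParams(complexity=cp)))
            for cp in (0.2, 0.05, 0.01, 0.002)
        ]
        assert counts == sorted(counts)


class TestSegmentWindow:
    def test_composition_counts(self, flat_rdm):
        rdm = flat_rdm
        rdm = rdm.slice_markers(np.arange(rdm.n_markers))
        rdm.sample_ids = ["A", "B"]
        step = np.concatenate([np.ones(200), np.full(100, 0.5)])
        rdm.rel_depth = np.column_stack([np.ones(300), step])
        segs = segment_window(rdm)
        assert len(segs) == 3
        assert sum(s.sample_id == "A" for s in segs) == 1
        assert sum(s.sample_id == "B" for s in segs) == 2

    def test_all_constant_one_segment_each(self, flat_rdm):
        segs = segment_window(flat_rdm)
        assert [s.sample_id for s in segs] == ["A", "B", "C"]

    def test_all_missing_sample_skipped(self, flat_rdm):
        flat_rdm.rel_depth[:, 1] = np.nan
        segs = segment_window(flat_rdm)
        assert [s.sample_id for s in segs] == ["A", "C"]

    def test_permuting_samples_permutes_output(self, small_rdm):
        segs = segment_window(small_rdm)
        perm = np.array([1, 0] + list(range(2, small_rdm.n_samples)))
        shuffled = type(small_rdm)(
            chromosome=small_rdm.chromosome,
            positions=small_rdm.positions,
            sample_ids=[small_rdm.sample_ids[i] for i in perm],
            rel_depth=small_rdm.rel_depth[:, perm],
            chrom_mean_depth=small_rdm.chrom_mean_depth[perm],
        )
        segs2 = segment_window(shuffled)
        key = lambda s: (s.sample_id, s.start_bp)
        as_tuples = lambda ss: sorted(
            (s.sample_id, s.start_bp, s.end_bp, s.n_markers, round(s.fitted_depth, 12))
            for s in ss
        )
        assert as_tuples(segs) == as_tuples(segs2)
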