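"""Per-sample piecewise-constant regression of relative depth.

Each sample's relative-depth signal inside a window is fitted with a
regression tree on genomic position: recursive binary splitting that accepts
a split only when it reduces the total sum of squared errors by at least
``complexity`` times the SSE of the root (single-segment) fit — the
rpart/anova convention — and only when both children keep at least
``min_leaf`` markers.  With the defaults (complexity 0.01, min_leaf 6) the
fit follows only broad depth changes, which is exactly what large germline
CNVs look like at marker resolution.

The tree is grown restrictively rather than grown large and pruned: the
complexity rule is applied during growth, there is no cross-validation
pruning pass.  Ties in best-split SSE are broken by the leftmost cut point
so the fit is fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .io_depth import RelativeDepthMatrix

logger = logging.getLogger(__name__)


@dataclass
class SegmentationParams:
    """Tree-growth controls: rpart cp and minbucket equivalents."""

    complexity: float = 0.01
    min_leaf: int = 6

    def __post_init__(self) -> None:
        if not (0 < self.complexity < 1):
            raise ValueError("complexity must be in (0, 1)")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")


@dataclass
class DepthSegment:
    """One constant piece of a sample's fit.

    start_bp/end_bp are the 1-based positions of the first and last member
    marker (inclusive); fitted_depth is the arithmetic mean of the member
    markers' relative depths.
    """

    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_markers: int
    fitted_depth: float

    @property
    def length_bp(self) -> int:
        """Span as a half-open interval: [start_bp - 1, end_bp)."""
        return self.end_bp - (self.start_bp - 1)


def _best_split(y, csum, csum2, lo, hi, min_leaf):
    """Best cut of node [lo, hi) into [lo, i) | [i, hi); returns (i, gain).

    gain is the SSE reduction of the cut versus the single-mean fit of the
    node.  Vectorised over every admissible cut; ties go to the leftmost
    cut.  Returns (None, 0.0) when no cut is admissible.
    """
    n = hi - lo
    if n < 2 * min_leaf:
        return None, 0.0
    # candidate left sizes min_leaf .. n - min_leaf
    i = np.arange(lo + min_leaf, hi - min_leaf + 1)
    s1l = csum[i] - csum[lo]
    s1r = (csum[hi] - csum[lo]) - s1l
    nl = i - lo
    nr = hi - i
    # node SSE = sum(y^2) - (sum y)^2 / n; the sum(y^2) terms cancel in the
    # gain, leaving only the between-means part
    tot = csum[hi] - csum[lo]
    gain = s1l * s1l / nl + s1r * s1r / nr - tot * tot / n
    k = int(np.argmax(gain))
    return int(i[k]), float(gain[k])


def _grow(y, csum, csum2, lo, hi, min_leaf, threshold, cuts):
    split, gain = _best_split(y, csum, csum2, lo, hi, min_leaf)
    if split is None or gain < threshold or gain <= 0.0:
        return
    cuts.append(split)
    _grow(y, csum, csum2, lo, split, min_leaf, threshold, cuts)
    _grow(y, csum, csum2, split, hi, min_leaf, threshold, cuts)


class PiecewiseConstantRegressor(BaseEstimator, RegressorMixin):
    """Regression-tree piecewise-constant fit of a 1-D signal on position.

    Parameters
    ----------
    complexity : float, default 0.01
        A split must reduce total SSE by at least ``complexity`` times the
        SSE of the root fit (the relative-r2 rule of rpart's anova method).
    min_leaf : int, default 6
        Minimum markers per piece (rpart minbucket); a node with fewer than
        ``2 * min_leaf`` markers is never split (rpart minsplit).

    Attributes
    ----------
    cut_indices_ : ndarray of int
        Sorted interior cut points (left piece is ``[.., cut)``).
    piece_means_ : ndarray of float
        Mean of each piece, left to right.
    piece_slices_ : list of (lo, hi) half-open index pairs.
    """

    def __init__(self, complexity: float = 0.01, min_leaf: int = 6):
        self.complexity = complexity
        self.min_leaf = min_leaf

    def fit(self, X, y):
        X = np.asarray(X)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("expected a single position feature")
            X = X[:, 0]
        y = np.asarray(y, dtype=np.float64)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if len(y) == 0:
            raise ValueError("empty input")
        if np.any(np.isnan(y)):
            raise ValueError("NaN depths must be filtered before fitting")
        if np.any(np.diff(X) < 0):
            raise ValueError("positions must be sorted")
        SegmentationParams(self.complexity, self.min_leaf)  # validate

        n = len(y)
        csum = np.concatenate([[0.0], np.cumsum(y)])
        csum2 = np.concatenate([[0.0], np.cumsum(y * y)])
        sse_root = float(csum2[n] - csum[n] ** 2 / n)
        threshold = self.complexity * sse_root
        cuts: list[int] = []
        _grow(y, csum, csum2, 0, n, self.min_leaf, threshold, cuts)
        cuts = sorted(cuts)
        bounds = [0, *cuts, n]
        self.positions_ = X
        self.cut_indices_ = np.array(cuts, dtype=np.int64)
        self.piece_slices_ = list(zip(bounds[:-1], bounds[1:]))
        self.piece_means_ = np.array(
            [(csum[hi] - csum[lo]) / (hi - lo) for lo, hi in self.piece_slices_]
        )
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        X = np.asarray(X)
        if X.ndim == 2:
            X = X[:, 0]
        # piece k covers positions in [pos[lo_k], pos[lo_{k+1}])
        starts = np.array([self.positions_[lo] for lo, _ in self.piece_slices_])
        idx = np.clip(np.searchsorted(starts, X, side="right") - 1, 0, len(starts) - 1)
        return self.piece_means_[idx]

    def segments(self, sample_id: str = "", chromosome: str = "") -> list[DepthSegment]:
        """The fitted pieces as :class:`DepthSegment` records."""
        return [
            DepthSegment(
                sample_id=sample_id,
                chromosome=chromosome,
                start_bp=int(self.positions_[lo]),
                end_bp=int(self.positions_[hi - 1]),
                n_markers=hi - lo,
                fitted_depth=float(mean),
            )
            for (lo, hi), mean in zip(self.piece_slices_, self.piece_means_)
        ]


def fit_piecewise_constant(
    positions,
    depths,
    params: SegmentationParams | None = None,
    sample_id: str = "",
    chromosome: str = "",
) -> list[DepthSegment]:
    """Fit one sample's depths; missing values must already be removed."""
    params = params or SegmentationParams()
    reg = PiecewiseConstantRegressor(params.complexity, params.min_leaf)
    reg.fit(np.asarray(positions), np.asarray(depths))
    return reg.segments(sample_id=sample_id, chromosome=chromosome)


def segment_window(
    window: RelativeDepthMatrix, params: SegmentationParams | None = None
) -> list[DepthSegment]:
    """Fit every sample in a window and pool the segments.

    Samples with no non-missing markers in the window contribute no
    segments (logged).  Fully deterministic: sample order follows the
    matrix, cut ties break leftmost.
    """
    params = params or SegmentationParams()
    out: list[DepthSegment] = []
    for j, sid in enumerate(window.sample_ids):
        col = window.rel_depth[:, j]
        keep = ~np.isnan(col)
        if not keep.any():
            logger.warning("sample %s has no usable markers in window", sid)
            continue
        out.extend(
            fit_piecewise_constant(
                window.positions[keep],
                col[keep],
                params,
                sample_id=sid,
                chromosome=window.chromosome,
            )
        )
    return out
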