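"""Population-level scoring of depth segments against half-integer states.

Pooled across samples, fitted segment depths cluster around multiples of 0.5
when depth anomalies are genuine copy-number states (relative depth 0.5*n).
A Gaussian mixture with means *fixed* at the multiples of 0.5 spanned by the
observed depth range is fitted by EM (weights and per-component standard
deviations free, means never move).  Each segment is then assigned the
nearest half-integer "ideal depth" and a score

    s = 2 * (1 - Phi(|fitted - ideal| / sd_component)),

twice the upper-tail probability of the standardised deviation under the
component centred on the ideal depth.  s is 1 when the segment sits exactly
on its state and decays towards 0 as it drifts away; a segment is
high-quality (HQ) when s > 0.1 (strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.base import BaseEstimator, DensityMixin

from .segment import DepthSegment

HQ_THRESHOLD = 0.1
SD_MIN = 0.01


def round_to_half(x: float) -> float:
    """Nearest non-negative multiple of 0.5; exact ties round toward 1.0.

    Preferring the state closer to diploid on a tie (0.75 -> 1.0,
    0.25 -> 0.5, 1.25 -> 1.0) is the conservative choice: a tie carries no
    evidence, so the null (diploid) wins.
    """
    lo = np.floor(x * 2.0) / 2.0
    hi = lo + 0.5
    lo = max(lo, 0.0)
    d_lo, d_hi = abs(x - lo), abs(x - hi)
    if d_lo < d_hi:
        return float(lo)
    if d_hi < d_lo:
        return float(hi)
    return float(hi if abs(hi - 1.0) <= abs(lo - 1.0) else lo)


@dataclass
class GaussianComponent:
    ideal_depth: float  # fixed mean, a multiple of 0.5
    sd: float
    weight: float


@dataclass
class ScoredSegment:
    segment: DepthSegment
    ideal_depth: float
    score: float
    is_hq: bool


class HalfGridMixture(BaseEstimator, DensityMixin):
    """Gaussian mixture with means fixed on the half-integer grid.

    The grid spans the multiples of 0.5 nearest to the smallest and largest
    observed depth (clipped at 0), so every observation's nearest
    half-integer has a component.  EM updates only weights and per-component
    sds; components are never dropped, however small their weight, so every
    ideal depth stays scoreable.  Initialisation is deterministic (uniform
    weights, sd 0.1); sds are floored at 0.01 to avoid singularities.

    Attributes
    ----------
    means_ : ndarray — the fixed half-integer grid.
    sds_, weights_ : ndarray — fitted per component.
    log_likelihoods_ : list of float — EM trajectory (non-decreasing).
    """

    def __init__(
        self,
        max_iter: int = 500,
        tol: float = 1e-8,
        init_sd: float = 0.1,
        sd_min: float = SD_MIN,
    ):
        self.max_iter = max_iter
        self.tol = tol
        self.init_sd = init_sd
        self.sd_min = sd_min

    @staticmethod
    def grid_for_range(lo: float, hi: float) -> np.ndarray:
        lo_half = round_to_half(lo)
        hi_half = round_to_half(hi)
        if hi_half < lo_half:
            lo_half, hi_half = hi_half, lo_half
        k = np.arange(round(lo_half * 2), round(hi_half * 2) + 1)
        return k / 2.0

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=np.float64).ravel()
        if len(x) == 0:
            raise ValueError("cannot fit a mixture to zero segments")
        self.means_ = self.grid_for_range(float(x.min()), float(x.max()))
        k = len(self.means_)
        w = np.full(k, 1.0 / k)
        sd = np.full(k, float(self.init_sd))
        lls: list[float] = []
        for _ in range(self.max_iter):
            # E step
            logpdf = norm.logpdf(x[:, None], loc=self.means_[None, :], scale=sd[None, :])
            with np.errstate(divide="ignore"):
                logw = np.log(w)
            joint = logpdf + logw[None, :]
            m = joint.max(axis=1, keepdims=True)
            lse = m[:, 0] + np.log(np.exp(joint - m).sum(axis=1))
            ll = float(lse.sum())
            resp = np.exp(joint - lse[:, None])
            lls.append(ll)
            if len(lls) > 1 and abs(lls[-1] - lls[-2]) < self.tol:
                break
            # M step: weights and sds only, means stay on the grid
            nk = resp.sum(axis=0)
            w = nk / len(x)
            dev2 = (x[:, None] - self.means_[None, :]) ** 2
            with np.errstate(invalid="ignore", divide="ignore"):
                new_var = (resp * dev2).sum(axis=0) / nk
            # components with no effective mass keep their previous sd
            dead = ~np.isfinite(new_var) | (nk < 1e-12)
            new_sd = np.sqrt(np.where(dead, sd**2, new_var))
            sd = np.maximum(new_sd, self.sd_min)
        self.weights_ = w
        self.sds_ = sd
        self.log_likelihoods_ = lls
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        """Index of the component whose mean is nearest each value."""
        x = np.asarray(X, dtype=np.float64).ravel()
        halves = np.array([round_to_half(v) for v in x])
        clipped = np.clip(halves, self.means_[0], self.means_[-1])
        return np.round((clipped - self.means_[0]) * 2).astype(int)

    def components(self) -> list[GaussianComponent]:
        return [
            GaussianComponent(float(m), float(s), float(w))
            for m, s, w in zip(self.means_, self.sds_, self.weights_)
        ]


def fit_constrained_mixture(
    segment_depths,
    window_range: tuple[float, float] | None = None,
) -> list[GaussianComponent]:
    """Fit the half-grid mixture to pooled segment depths.

    ``window_range`` overrides the observed (min, max) when the grid should
    span a wider range than the depths at hand.  All-identical depths give a
    single-component degenerate fit with sd floored at 0.01.
    """
    x = np.asarray(segment_depths, dtype=np.float64).ravel()
    if len(x) == 0:
        raise ValueError("cannot fit a mixture to zero segments")
    lo, hi = float(x.min()), float(x.max())
    if window_range is not None:
        lo, hi = min(lo, window_range[0]), max(hi, window_range[1])
    grid = HalfGridMixture.grid_for_range(lo, hi)

    class _FixedGrid(HalfGridMixture):
        @staticmethod
        def grid_for_range(a, b):  # noqa: ARG004 — grid supplied externally
            return grid

    return _FixedGrid().fit(x).components()


def _component_for(ideal: float, components: list[GaussianComponent]) -> GaussianComponent:
    best = min(components, key=lambda c: abs(c.ideal_depth - ideal))
    return best


def score_segment(
    seg: DepthSegment, components: list[GaussianComponent]
) -> ScoredSegment:
    """Assign the nearest half-integer state and the score s = 2p."""
    ideal = round_to_half(seg.fitted_depth)
    comp = _component_for(ideal, components)
    z = abs(seg.fitted_depth - ideal) / comp.sd
    p = float(norm.sf(z))
    s = 2.0 * p
    return ScoredSegment(segment=seg, ideal_depth=ideal, score=s, is_hq=s > HQ_THRESHOLD)


def score_segments(
    segments: list[DepthSegment], components: list[GaussianComponent]
) -> list[ScoredSegment]:
    return [score_segment(s, components) for s in segments]
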