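"""Turn scored segments into called CNV regions by chunk voting and RLE.

The window is discretised into fixed-width chunks (default 5 kb).  A chunk
supports a depth anomaly when the high-quality non-diploid segments that
overlap it outnumber the low-quality ones (ratio > ratio_threshold, default
1); with zero low-quality segments a single high-quality segment suffices —
even a singleton carrier is called.  Maximal runs of supporting chunks
(run-length encoding) become called regions; chunk width therefore bounds
boundary precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .score import ScoredSegment


@dataclass
class ChunkSupport:
    """Anomaly vote for one half-open chunk [chunk_start, chunk_end)."""

    chunk_start: int
    chunk_end: int
    n_hq_nondiploid: int
    n_lq_nondiploid: int
    supports_anomaly: bool


@dataclass
class CNVRegion:
    """A called variable region, snapped to chunk boundaries (half-open)."""

    chromosome: str
    start_bp: int
    end_bp: int
    event_class: str  # deletion | duplication | mixed
    n_supporting_chunks: int
    edge: bool = False
    qc_pass: bool = True

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def make_chunk_grid(window_start: int, window_end: int, chunk_bp: int) -> list[tuple[int, int]]:
    """Half-open chunks tiling [window_start, window_end); the final chunk
    may be partial and is kept."""
    grid = []
    s = window_start
    while s < window_end:
        grid.append((s, min(s + chunk_bp, window_end)))
        s += chunk_bp
    return grid


def _overlaps(seg, c0: int, c1: int) -> bool:
    # segment spans [start_bp - 1, end_bp) half-open (1-based inclusive marker coords)
    return seg.start_bp - 1 < c1 and seg.end_bp > c0


def chunk_support(
    chunks: list[tuple[int, int]],
    scored: list[ScoredSegment],
    ratio_threshold: float = 1.0,
) -> list[ChunkSupport]:
    """Vote each chunk using the non-diploid segments that overlap it.

    Only segments with ideal depth != 1.0 count (any-overlap attribution —
    the most sensitive choice).  Support iff HQ/LQ > ratio_threshold, with
    the zero-LQ convention that any HQ count >= 1 supports.
    """
    n = len(chunks)
    starts = np.array([c0 for c0, _ in chunks])
    ends = np.array([c1 for _, c1 in chunks])
    hq_cnt = np.zeros(n + 1, dtype=np.int64)
    lq_cnt = np.zeros(n + 1, dtype=np.int64)
    for s in scored:
        if s.ideal_depth == 1.0:
            continue
        s0, e = s.segment.start_bp - 1, s.segment.end_bp  # half-open span
        first = int(np.searchsorted(ends, s0, side="right"))
        last = int(np.searchsorted(starts, e, side="left")) - 1
        if first > last or first >= n or last < 0:
            continue
        tgt = hq_cnt if s.is_hq else lq_cnt
        tgt[first] += 1
        tgt[last + 1] -= 1
    hq = np.cumsum(hq_cnt[:-1])
    lq = np.cumsum(lq_cnt[:-1])
    out = []
    for i, (c0, c1) in enumerate(chunks):
        if lq[i] == 0:
            supports = hq[i] >= 1
        else:
            supports = hq[i] / lq[i] > ratio_threshold
        out.append(ChunkSupport(c0, c1, int(hq[i]), int(lq[i]), bool(supports)))
    return out


def rle_regions(
    support: list[ChunkSupport],
    scored: list[ScoredSegment],
    chromosome: str = "",
) -> list[CNVRegion]:
    """Run-length-encode supporting chunks into maximal regions.

    Event class is decided by the HQ non-diploid segments overlapping the
    run: all below diploid -> deletion, all above -> duplication, else mixed.
    Runs touching the first or last chunk are flagged ``edge`` so adjacent
    windows can be merged in a post-pass.
    """
    hq_nondip = [s for s in scored if s.is_hq and s.ideal_depth != 1.0]
    regions: list[CNVRegion] = []
    i = 0
    n = len(support)
    while i < n:
        if not support[i].supports_anomaly:
            i += 1
            continue
        j = i
        while j + 1 < n and support[j + 1].supports_anomaly:
            j += 1
        start, end = support[i].chunk_start, support[j].chunk_end
        ideals = {
            s.ideal_depth for s in hq_nondip if _overlaps(s.segment, start, end)
        }
        if ideals and all(d < 1.0 for d in ideals):
            cls = "deletion"
        elif ideals and all(d > 1.0 for d in ideals):
            cls = "duplication"
        else:
            cls = "mixed"
        regions.append(
            CNVRegion(
                chromosome=chromosome,
                start_bp=start,
                end_bp=end,
                event_class=cls,
                n_supporting_chunks=j - i + 1,
                edge=(i == 0 or j == n - 1),
            )
        )
        i = j + 1
    return regions


def filter_deletion_only(scored: list[ScoredSegment]) -> list[ScoredSegment]:
    """Keep only segments supporting deletions (ideal depth < 1).

    Applied before chunk voting in deletion-only mode; every region called
    from the filtered set is a deletion by construction.
    """
    return [s for s in scored if s.ideal_depth < 1.0]
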