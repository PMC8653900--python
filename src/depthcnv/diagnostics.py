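"""Optional diagnostic plots (requires matplotlib, not a core dependency).

Visual QC mirrors how array genotypes are reviewed via cluster plots: a
per-sample depth trace with its piecewise fit, the pooled segments of a
window coloured by assigned ideal depth, and a genotype cluster strip per
region.  Plots never influence calling results.
"""

from __future__ import annotations

import numpy as np

from .io_depth import RelativeDepthMatrix
from .score import ScoredSegment

_IDEAL_COLORS = {0.0: "tab:red", 0.5: "tab:blue", 1.0: "tab:green", 1.5: "tab:purple"}


def _require_pyplot():
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
    except ImportError as e:  # pragma: no cover
        raise ImportError("diagnostic plots need matplotlib (pip install depthcnv[plot])") from e
    return plt


def plot_sample_fit(rdm: RelativeDepthMatrix, sample_id: str, scored: list[ScoredSegment], path):
    """Raw relative depth for one sample with its piecewise fit overlaid."""
    plt = _require_pyplot()
    j = rdm.sample_ids.index(sample_id)
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.plot(rdm.positions, rdm.rel_depth[:, j], ".", ms=1, color="0.7")
    for s in scored:
        if s.segment.sample_id == sample_id:
            ax.hlines(s.segment.fitted_depth, s.segment.start_bp, s.segment.end_bp,
                      color="red", lw=2)
    ax.set(xlabel="position (bp)", ylabel="relative depth", ylim=(-0.1, 2.5))
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_pooled_segments(scored: list[ScoredSegment], path):
    """All samples' segments, coloured by assigned ideal depth."""
    plt = _require_pyplot()
    fig, ax = plt.subplots(figsize=(10, 3))
    for s in scored:
        c = _IDEAL_COLORS.get(s.ideal_depth, "tab:orange")
        ax.hlines(s.segment.fitted_depth, s.segment.start_bp, s.segment.end_bp,
                  color=c, lw=1, alpha=0.5)
    ax.set(xlabel="position (bp)", ylabel="fitted relative depth")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_genotype_clusters(genotypes, rdm: RelativeDepthMatrix, path):
    """Mean in-region depth per sample, coloured by assigned copy number."""
    plt = _require_pyplot()
    fig, ax = plt.subplots(figsize=(5, 3))
    region = genotypes[0].region
    sel = (rdm.positions > region.start_bp) & (rdm.positions <= region.end_bp)
    for g in genotypes:
        j = rdm.sample_ids.index(g.sample_id)
        mean = np.nanmean(rdm.rel_depth[sel, j])
        color = "0.5" if g.missing else _IDEAL_COLORS.get((g.copy_number or 0) / 2, "tab:orange")
        ax.plot(np.random.default_rng(j).uniform(-0.3, 0.3), mean, "o", ms=3, color=color)
    ax.set(ylabel="mean relative depth", xticks=[],
           title=f"{region.chromosome}:{region.start_bp}-{region.end_bp}")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
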