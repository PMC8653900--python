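"""Per-sample copy-number genotyping of called regions.

Two genotypers are provided.  *Segment-based*: the length-weighted mean of a
sample's assigned (ideal) segment depths over the region, rounded to the
nearest multiple of 0.5; its quality is the length-weighted mean of segment
scores (higher is better).  *Means-based*: the nearest multiple of 0.5 to
the sample's mean marker relative depth across the region; its quality is
the distance between mean and assigned depth (smaller is better).  The
means-based route is robust at the detection limit, where not every carrier
shows an abnormal segment; a manual genotyper applies it to user-specified
coordinates.  Copy number is 2 x assigned depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .callregions import CNVRegion
from .io_depth import RelativeDepthMatrix
from .score import ScoredSegment, round_to_half

logger = logging.getLogger(__name__)


@dataclass
class CNVGenotype:
    sample_id: str
    region: CNVRegion
    assigned_depth: float | None  # multiple of 0.5, None when missing
    copy_number: int | None
    quality: float | None
    method: str  # segment | means | manual
    n_segments: int = 0
    missing: bool = False


@dataclass
class GenotypeQCParams:
    """Thresholds for flagging unreliable genotypes as missing.

    Too many segments means the sample's depth in the region was complex
    (multiple breaks); too low an aggregate score (segment method) or too
    large a mean-to-assigned distance (means method) means the assignment
    was ambiguous.
    """

    max_segments: int = 4
    min_quality: float = 0.1  # segment-based aggregate score, lower bound
    max_distance: float = 0.2  # means-based |mean - assigned|, upper bound


def _clip_overlap_bp(seg, start: int, end: int) -> int:
    # segment occupies [start_bp - 1, end_bp) half-open
    return max(0, min(seg.end_bp, end) - max(seg.start_bp - 1, start))


def genotype_segment_based(
    sample_id: str,
    region: CNVRegion,
    sample_segments: list[ScoredSegment],
    max_ideal: float | None = None,
) -> CNVGenotype:
    """Length-weighted vote of the sample's scored segments over the region.

    Segments are clipped to the region before weighting so a long flanking
    diploid segment cannot swamp the event.  ``max_ideal`` caps the assigned
    depth at the mixture's largest component.
    """
    weights, ideals, scores = [], [], []
    for s in sample_segments:
        w = _clip_overlap_bp(s.segment, region.start_bp, region.end_bp)
        if w > 0:
            weights.append(w)
            ideals.append(s.ideal_depth)
            scores.append(s.score)
    if not weights:
        logger.debug("no segments overlap region for %s; genotype missing", sample_id)
        return CNVGenotype(sample_id, region, None, None, None, "segment", 0, True)
    w = np.array(weights, dtype=np.float64)
    mean_ideal = float(np.dot(w, ideals) / w.sum())
    quality = float(np.dot(w, scores) / w.sum())
    assigned = round_to_half(mean_ideal)
    if max_ideal is not None:
        assigned = min(assigned, max_ideal)
    return CNVGenotype(
        sample_id,
        region,
        assigned,
        int(round(2 * assigned)),
        quality,
        "segment",
        n_segments=len(weights),
    )


def genotype_means_based(
    sample_id: str,
    region: CNVRegion,
    rdm: RelativeDepthMatrix,
    method: str = "means",
    max_ideal: float | None = None,
) -> CNVGenotype:
    """Nearest half-integer to the mean marker relative depth in the region."""
    j = rdm.sample_ids.index(sample_id)
    in_region = (rdm.positions > region.start_bp) & (rdm.positions <= region.end_bp)
    vals = rdm.rel_depth[in_region, j]
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        return CNVGenotype(sample_id, region, None, None, None, method, 0, True)
    mean = float(vals.mean())
    assigned = round_to_half(mean)
    if max_ideal is not None:
        assigned = min(assigned, max_ideal)
    return CNVGenotype(
        sample_id,
        region,
        assigned,
        int(round(2 * assigned)),
        abs(mean - assigned),
        method,
        n_segments=0,
    )


def manual_genotype(
    chromosome: str,
    start_bp: int,
    end_bp: int,
    rdm: RelativeDepthMatrix,
) -> list[CNVGenotype]:
    """Means-based genotyping of every sample over a user interval.

    ``start_bp``/``end_bp`` are 0-based half-open, matching region output.
    A marker desert (no markers in the interval) is a hard error.
    """
    in_region = (rdm.positions > start_bp) & (rdm.positions <= end_bp)
    if not in_region.any():
        raise ValueError(
            f"no markers in {chromosome}:{start_bp}-{end_bp}; cannot genotype"
        )
    region = CNVRegion(
        chromosome=chromosome,
        start_bp=start_bp,
        end_bp=end_bp,
        event_class="manual",
        n_supporting_chunks=0,
    )
    return [
        genotype_means_based(s, region, rdm, method="manual")
        for s in rdm.sample_ids
    ]


def apply_genotype_qc(
    genotypes: list[CNVGenotype], qc: GenotypeQCParams | None = None
) -> list[CNVGenotype]:
    """Flag unreliable genotypes as missing (idempotent).

    Segment-based genotypes fail on too many segments or too low a score;
    means-based (and manual) fail on too large a mean-to-assigned distance.
    """
    qc = qc or GenotypeQCParams()
    out = []
    newly_missing = 0
    for g in genotypes:
        fail = False
        if not g.missing:
            if g.method == "segment":
                fail = g.n_segments > qc.max_segments or g.quality < qc.min_quality
            else:
                fail = g.quality > qc.max_distance
        if fail:
            newly_missing += 1
            out.append(
                CNVGenotype(
                    g.sample_id, g.region, None, None, g.quality, g.method,
                    g.n_segments, True,
                )
            )
        else:
            out.append(g)
    if newly_missing:
        logger.info("genotype QC set %d genotypes to missing", newly_missing)
    return out


def allele_frequency(genotypes: list[CNVGenotype]) -> float | None:
    """Deletion allele frequency under a biallelic model.

    AF = (2 * n_CN0 + n_CN1) / (2 * n_nonmissing); None when every genotype
    is missing.
    """
    n0 = n1 = total = 0
    for g in genotypes:
        if g.missing or g.copy_number is None:
            continue
        total += 1
        if g.copy_number == 0:
            n0 += 1
        elif g.copy_number == 1:
            n1 += 1
    if total == 0:
        return None
    return (2 * n0 + n1) / (2 * total)
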