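"""Read per-sample marker depth from multi-sample VCFs and normalise it.

The caller operates on *relative* depth: each sample's raw FORMAT/DP value at
a marker, divided by that sample's chromosome-wide mean depth.  Under the
copy-number model the expectation of relative depth is 0.5*n for copy number
n, so 1.0 marks the diploid state.  Only biallelic SNVs are used as markers:
their spacing is what bounds the boundary precision of the caller, and indels
have less reliable depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pysam

logger = logging.getLogger(__name__)

_BASES = {"A", "C", "G", "T"}


@dataclass
class MarkerDepthMatrix:
    """Raw per-marker, per-sample read depth for one chromosome.

    ``depth`` is a float matrix of shape (n_markers, n_samples); missing DP
    entries are NaN (never silently zero).  Positions are 1-based and
    strictly increasing.
    """

    chromosome: str
    positions: np.ndarray
    sample_ids: list[str]
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=np.float64)
        if self.depth.shape != (len(self.positions), len(self.sample_ids)):
            raise ValueError(
                f"depth shape {self.depth.shape} does not match "
                f"{len(self.positions)} markers x {len(self.sample_ids)} samples"
            )
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("marker positions must be strictly increasing")
        with np.errstate(invalid="ignore"):
            if np.any(self.depth < 0):
                raise ValueError("raw depths must be >= 0")

    @property
    def n_markers(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class RelativeDepthMatrix:
    """Depth normalised by each sample's chromosome-wide mean depth.

    ``rel_depth[i, j] = raw[i, j] / chrom_mean_depth[j]``; the per-sample
    mean of ``rel_depth`` over non-missing markers is exactly 1 when the
    normaliser was computed on this marker set.
    """

    chromosome: str
    positions: np.ndarray
    sample_ids: list[str]
    rel_depth: np.ndarray
    chrom_mean_depth: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.rel_depth = np.asarray(self.rel_depth, dtype=np.float64)
        self.chrom_mean_depth = np.asarray(self.chrom_mean_depth, dtype=np.float64)

    @property
    def n_markers(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def slice_markers(self, idx: np.ndarray) -> "RelativeDepthMatrix":
        """A view-like slice over a marker index array (samples untouched)."""
        return RelativeDepthMatrix(
            chromosome=self.chromosome,
            positions=self.positions[idx],
            sample_ids=self.sample_ids,
            rel_depth=self.rel_depth[idx],
            chrom_mean_depth=self.chrom_mean_depth,
        )


def _is_biallelic_snv(ref: str, alts) -> bool:
    if alts is None or len(alts) != 1:
        return False
    alt = alts[0]
    return ref in _BASES and isinstance(alt, str) and alt in _BASES


def read_vcf_depths(
    vcf_path,
    chromosome: str,
    region: tuple[int, int] | None = None,
) -> MarkerDepthMatrix:
    """Read FORMAT/DP for every sample at biallelic SNV records.

    Parameters
    ----------
    vcf_path
        Plain or bgzipped VCF.  A tabix index is used for ``region`` queries
        when present; otherwise records are filtered while streaming.
    chromosome
        Chromosome (contig) to read.
    region
        Optional 1-based inclusive (start, end) restriction.

    Multiallelic and non-SNV records are skipped (counts logged), as are
    records where every sample is missing DP.  A record whose FORMAT lacks DP
    entirely is a hard error, as is an unsorted VCF.
    """
    vcf = pysam.VariantFile(str(vcf_path))
    if "DP" not in vcf.header.formats:
        raise ValueError(f"{vcf_path}: FORMAT/DP not declared in header")
    sample_ids = list(vcf.header.samples)
    if not sample_ids:
        raise ValueError(f"{vcf_path}: no samples in VCF")

    fetch_kwargs = {}
    iterator = None
    if region is not None and vcf.index is not None:
        # tabix/csi region query; pysam uses 0-based half-open internally
        iterator = vcf.fetch(chromosome, region[0] - 1, region[1])
    else:
        iterator = vcf

    positions: list[int] = []
    rows: list[np.ndarray] = []
    skipped = {"other_chrom": 0, "multiallelic": 0, "non_snv": 0, "all_missing": 0}
    last_pos = -1
    for rec in iterator:
        if rec.chrom != chromosome:
            skipped["other_chrom"] += 1
            continue
        if region is not None and not (region[0] <= rec.pos <= region[1]):
            continue
        if rec.alts is not None and len(rec.alts) > 1:
            skipped["multiallelic"] += 1
            continue
        if not _is_biallelic_snv(rec.ref, rec.alts):
            skipped["non_snv"] += 1
            continue
        if rec.pos < last_pos:
            raise ValueError(
                f"{vcf_path}: unsorted VCF at {rec.chrom}:{rec.pos} "
                f"(previous position {last_pos})"
            )
        last_pos = rec.pos
        if "DP" not in rec.format.keys():
            raise ValueError(
                f"{vcf_path}: record {rec.chrom}:{rec.pos} has no DP in FORMAT"
            )
        row = np.full(len(sample_ids), np.nan)
        for j, s in enumerate(sample_ids):
            dp = rec.samples[s].get("DP")
            if dp is not None:
                row[j] = float(dp)
        if np.all(np.isnan(row)):
            skipped["all_missing"] += 1
            continue
        positions.append(rec.pos)
        rows.append(row)
    vcf.close()

    for cls, n in skipped.items():
        if n:
            logger.info("read_vcf_depths(%s): skipped %d %s records", chromosome, n, cls)

    depth = (
        np.array(rows) if rows else np.empty((0, len(sample_ids)), dtype=np.float64)
    )
    return MarkerDepthMatrix(
        chromosome=chromosome,
        positions=np.array(positions, dtype=np.int64),
        sample_ids=sample_ids,
        depth=depth,
    )


def normalize_relative_depth(
    m: MarkerDepthMatrix, stat: str = "mean"
) -> RelativeDepthMatrix:
    """Divide each sample's depths by its chromosome-wide mean (or median).

    The normaliser is computed over the non-missing entries of the *whole
    chromosome* matrix (after marker filtering), never per window.  Missing
    entries stay missing.  A sample with zero chromosome-wide depth is a hard
    error — there is no meaningful relative depth for it.
    """
    if stat not in ("mean", "median"):
        raise ValueError(f"stat must be 'mean' or 'median', got {stat!r}")
    if m.n_markers == 0:
        raise ValueError("cannot normalise an empty matrix")
    with np.errstate(invalid="ignore"):
        if stat == "mean":
            norm = np.nanmean(m.depth, axis=0)
        else:
            norm = np.nanmedian(m.depth, axis=0)
    bad = [
        s
        for s, v in zip(m.sample_ids, norm)
        if not np.isfinite(v) or v <= 0
    ]
    if bad:
        raise ValueError(
            "samples with zero or undefined chromosome-wide depth: "
            + ", ".join(bad)
        )
    return RelativeDepthMatrix(
        chromosome=m.chromosome,
        positions=m.positions.copy(),
        sample_ids=list(m.sample_ids),
        rel_depth=m.depth / norm[None, :],
        chrom_mean_depth=norm,
    )


def iter_windows(rdm: RelativeDepthMatrix, window_bp: int):
    """Tile the chromosome with half-open windows [k*W, (k+1)*W).

    Yields ``(window_start_bp, slice)`` pairs covering every marker exactly
    once; intermediate windows without markers are yielded with an empty
    slice (real genomes have marker deserts, e.g. around centromeres).
    Window starts are 0-based; a 1-based marker position p falls in window
    ``(p - 1) // window_bp``.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    if rdm.n_markers == 0:
        return
    win_idx = (rdm.positions - 1) // window_bp
    last = int(win_idx[-1])
    for k in range(last + 1):
        sel = np.flatnonzero(win_idx == k)
        yield int(k) * window_bp, rdm.slice_markers(sel)
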