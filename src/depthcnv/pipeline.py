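"""Windowed orchestration: normalise, segment, score, call, genotype.

The chromosome is processed in fixed windows (default 10 Mb — large enough
that, at cohort sample sizes, the restrictive tree settings only follow
broad depth changes).  Windows are independent, so they parallelise
trivially; results are assembled in window order and are identical for any
worker count.  Regions touching a window edge are merged with a matching
edge region of the adjacent window when separated by less than one chunk.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed
from sklearn.base import BaseEstimator

from .callregions import (
    CNVRegion,
    chunk_support,
    filter_deletion_only,
    make_chunk_grid,
    rle_regions,
)
from .genotype import (
    CNVGenotype,
    GenotypeQCParams,
    allele_frequency,
    apply_genotype_qc,
    genotype_means_based,
    genotype_segment_based,
)
from .io_depth import (
    RelativeDepthMatrix,
    iter_windows,
    normalize_relative_depth,
    read_vcf_depths,
)
from .score import (
    GaussianComponent,
    ScoredSegment,
    fit_constrained_mixture,
    score_segments,
)
from .segment import SegmentationParams, segment_window

logger = logging.getLogger(__name__)

# windows where every fitted segment sits this close to diploid skip the
# mixture fit; every ideal depth would be 1.0, so no region can be called
DIPLOID_SHORTCUT_TOL = 0.15


@dataclass
class PipelineConfig:
    """Tunable parameters of the caller.

    window_bp should be increased when the cohort is small (<100 samples);
    chunk_bp sets boundary precision and should not drop below the minimum
    inter-SNV distance; ratio_threshold can be raised above 1 on noisy
    depth signals; complexity is the main sensitivity dial (smaller values
    follow depth more closely, catching smaller events at the cost of false
    positives).
    """

    window_bp: int = 10_000_000
    chunk_bp: int = 5_000
    complexity: float = 0.01
    min_leaf: int = 6
    ratio_threshold: float = 1.0
    mode: str = "all"  # all | deletion-only
    genotyper: str = "segment"  # segment | means
    max_segments: int = 4
    min_quality: float = 0.1
    max_distance: float = 0.2
    norm_stat: str = "mean"
    threads: int = 1
    seed: int = 0  # simulation only

    def __post_init__(self) -> None:
        if self.mode not in ("all", "deletion-only"):
            raise ValueError("mode must be 'all' or 'deletion-only'")
        if self.genotyper not in ("segment", "means"):
            raise ValueError("genotyper must be 'segment' or 'means'")
        if self.window_bp < 10 * self.chunk_bp:
            raise ValueError("window_bp must be >= 10 * chunk_bp")

    @property
    def segmentation(self) -> SegmentationParams:
        return SegmentationParams(self.complexity, self.min_leaf)

    @property
    def genotype_qc(self) -> GenotypeQCParams:
        return GenotypeQCParams(self.max_segments, self.min_quality, self.max_distance)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class WindowResult:
    window_start: int
    regions: list[CNVRegion]
    scored: list[ScoredSegment]
    components: list[GaussianComponent]


@dataclass
class PipelineResult:
    regions: list[CNVRegion]
    genotypes: dict[int, list[CNVGenotype]]  # region index -> per-sample
    allele_frequencies: dict[int, float | None]
    scored_segments: list[ScoredSegment]
    rdm: RelativeDepthMatrix

    def genotype_frame(self) -> pd.DataFrame:
        """regions x samples copy-number matrix; NaN marks missing."""
        rows = {}
        for i, r in enumerate(self.regions):
            name = f"{r.chromosome}:{r.start_bp}-{r.end_bp}"
            rows[name] = {
                g.sample_id: (np.nan if g.missing else g.copy_number)
                for g in self.genotypes[i]
            }
        return pd.DataFrame.from_dict(rows, orient="index")


def _process_window(window_start, window, params, window_bp, chunk_bp, ratio_threshold, mode):
    segments = segment_window(window, params)
    if not segments:
        return WindowResult(window_start, [], [], [])
    depths = np.array([s.fitted_depth for s in segments])
    if np.all(np.abs(depths - 1.0) <= DIPLOID_SHORTCUT_TOL):
        comps = [GaussianComponent(1.0, max(float(depths.std()), 0.01), 1.0)]
        scored = score_segments(segments, comps)
        return WindowResult(window_start, [], scored, comps)
    comps = fit_constrained_mixture(depths)
    scored = score_segments(segments, comps)
    callable_scored = (
        filter_deletion_only(scored) if mode == "deletion-only" else scored
    )
    grid = make_chunk_grid(window_start, window_start + window_bp, chunk_bp)
    support = chunk_support(grid, callable_scored, ratio_threshold)
    regions = rle_regions(support, callable_scored, chromosome=window.chromosome)
    if mode == "deletion-only":
        for r in regions:
            r.event_class = "deletion"
    return WindowResult(window_start, regions, scored, comps)


def _merge_edge_regions(results: list[WindowResult], chunk_bp: int) -> list[CNVRegion]:
    regions: list[CNVRegion] = []
    for res in results:
        regions.extend(res.regions)
    regions.sort(key=lambda r: (r.chromosome, r.start_bp))
    merged: list[CNVRegion] = []
    for r in regions:
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev.chromosome == r.chromosome
            and prev.edge
            and r.edge
            and 0 <= r.start_bp - prev.end_bp < chunk_bp
        ):
            cls = prev.event_class if prev.event_class == r.event_class else "mixed"
            merged[-1] = CNVRegion(
                chromosome=prev.chromosome,
                start_bp=prev.start_bp,
                end_bp=r.end_bp,
                event_class=cls,
                n_supporting_chunks=prev.n_supporting_chunks + r.n_supporting_chunks,
                edge=False,
            )
        else:
            merged.append(r)
    return merged


def call_cohort(rdm: RelativeDepthMatrix, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full caller on an in-memory relative-depth matrix."""
    config = config or PipelineConfig()
    params = config.segmentation
    windows = [
        (ws, w) for ws, w in iter_windows(rdm, config.window_bp) if w.n_markers > 0
    ]
    worker = delayed(_process_window)
    results = Parallel(n_jobs=config.threads, prefer="processes" if config.threads > 1 else None)(
        worker(ws, w, params, config.window_bp, config.chunk_bp, config.ratio_threshold, config.mode)
        for ws, w in windows
    )
    results = sorted(results, key=lambda r: r.window_start)
    regions = _merge_edge_regions(results, config.chunk_bp)
    all_scored: list[ScoredSegment] = []
    for res in results:
        all_scored.extend(res.scored)

    # largest mixture component seen anywhere caps assigned depths
    max_ideal = None
    comps = [c.ideal_depth for res in results for c in res.components]
    if comps:
        max_ideal = max(comps)

    by_sample: dict[str, list[ScoredSegment]] = {s: [] for s in rdm.sample_ids}
    for s in all_scored:
        by_sample[s.segment.sample_id].append(s)

    genotypes: dict[int, list[CNVGenotype]] = {}
    afs: dict[int, float | None] = {}
    for i, region in enumerate(regions):
        if config.genotyper == "segment":
            gts = [
                genotype_segment_based(sid, region, by_sample[sid], max_ideal=max_ideal)
                for sid in rdm.sample_ids
            ]
        else:
            gts = [
                genotype_means_based(sid, region, rdm, max_ideal=max_ideal)
                for sid in rdm.sample_ids
            ]
        gts = apply_genotype_qc(gts, config.genotype_qc)
        genotypes[i] = gts
        afs[i] = allele_frequency(gts) if region.event_class == "deletion" else None
    return PipelineResult(regions, genotypes, afs, all_scored, rdm)


class CNVCaller(BaseEstimator):
    """Estimator facade over the whole pipeline.

    ``fit`` takes a :class:`RelativeDepthMatrix` and exposes the called
    regions, per-sample genotypes and deletion allele frequencies as fitted
    attributes.  Parameters mirror :class:`PipelineConfig`.
    """

    def __init__(
        self,
        window_bp: int = 10_000_000,
        chunk_bp: int = 5_000,
        complexity: float = 0.01,
        min_leaf: int = 6,
        ratio_threshold: float = 1.0,
        mode: str = "all",
        genotyper: str = "segment",
        max_segments: int = 4,
        min_quality: float = 0.1,
        max_distance: float = 0.2,
        threads: int = 1,
    ):
        self.window_bp = window_bp
        self.chunk_bp = chunk_bp
        self.complexity = complexity
        self.min_leaf = min_leaf
        self.ratio_threshold = ratio_threshold
        self.mode = mode
        self.genotyper = genotyper
        self.max_segments = max_segments
        self.min_quality = min_quality
        self.max_distance = max_distance
        self.threads = threads

    def _config(self) -> PipelineConfig:
        return PipelineConfig(
            window_bp=self.window_bp,
            chunk_bp=self.chunk_bp,
            complexity=self.complexity,
            min_leaf=self.min_leaf,
            ratio_threshold=self.ratio_threshold,
            mode=self.mode,
            genotyper=self.genotyper,
            max_segments=self.max_segments,
            min_quality=self.min_quality,
            max_distance=self.max_distance,
            threads=self.threads,
        )

    def fit(self, X: RelativeDepthMatrix, y=None):
        result = call_cohort(X, self._config())
        self.result_ = result
        self.regions_ = result.regions
        self.genotypes_ = result.genotypes
        self.allele_frequencies_ = result.allele_frequencies
        self.scored_segments_ = result.scored_segments
        return self

    def predict(self, X: RelativeDepthMatrix):
        """Copy-number matrix (regions x samples) for the fitted regions,
        genotyped means-based on new depth data."""
        cns = []
        for region in self.regions_:
            row = [
                genotype_means_based(s, region, X).copy_number for s in X.sample_ids
            ]
            cns.append(row)
        return np.array(cns, dtype=object)


def run_pipeline(
    vcf_path,
    chromosome: str,
    config: PipelineConfig | None = None,
    out_prefix: str | None = None,
) -> PipelineResult:
    """Read a VCF, call and genotype CNVs, optionally write all outputs."""
    config = config or PipelineConfig()
    m = read_vcf_depths(vcf_path, chromosome)
    rdm = normalize_relative_depth(m, stat=config.norm_stat)
    result = call_cohort(rdm, config)
    if out_prefix is not None:
        write_outputs(result, out_prefix)
    return result


# ---------------------------------------------------------------- output I/O


def write_outputs(result: PipelineResult, prefix: str) -> None:
    prefix = str(prefix)
    write_regions_bed(result, prefix + ".regions.bed")
    write_regions_tsv(result, prefix + ".regions.tsv")
    result.genotype_frame().to_csv(prefix + ".genotypes.tsv", sep="\t", na_rep=".")
    write_cnv_vcf(result, prefix + ".cnv.vcf")


def write_regions_bed(result: PipelineResult, path) -> None:
    """BED (0-based half-open), name=event class, score=supporting chunks."""
    with open(path, "w") as fh:
        fh.write("#coordinates: 0-based half-open\n")
        for r in result.regions:
            fh.write(
                f"{r.chromosome}\t{r.start_bp}\t{r.end_bp}\t{r.event_class}\t"
                f"{r.n_supporting_chunks}\n"
            )


def write_regions_tsv(result: PipelineResult, path) -> None:
    rows = []
    for i, r in enumerate(result.regions):
        rows.append(
            {
                "chrom": r.chromosome,
                "start": r.start_bp,
                "end": r.end_bp,
                "event_class": r.event_class,
                "n_supporting_chunks": r.n_supporting_chunks,
                "edge": r.edge,
                "deletion_af": result.allele_frequencies.get(i),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_segments_tsv(scored: list[ScoredSegment], path) -> None:
    rows = [
        {
            "sample": s.segment.sample_id,
            "chrom": s.segment.chromosome,
            "start": s.segment.start_bp,
            "end": s.segment.end_bp,
            "n_markers": s.segment.n_markers,
            "fitted_depth": s.segment.fitted_depth,
            "ideal_depth": s.ideal_depth,
            "score": s.score,
            "is_hq": s.is_hq,
        }
        for s in scored
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_cnv_vcf(result: PipelineResult, path) -> None:
    """Symbolic-ALT VCF (1-based): <DEL>/<DUP>, per-sample GT/CN/quality.

    Deletions map CN 2/1/0 to GT 0/0, 0/1, 1/1; duplications (and mixed
    regions) get GT '.' with CN only — a biallelic GT is ill-defined there.
    """
    samples = result.rdm.sample_ids
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={result.rdm.chromosome}>\n")
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##ALT=<ID=DUP,Description="Duplication">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End (1-based inclusive)">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=CN,Number=1,Type=Integer,Description="Copy number">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Float,Description="Genotype quality">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        gt_map = {2: "0/0", 1: "0/1", 0: "1/1"}
        for i, r in enumerate(result.regions):
            svtype = "DEL" if r.event_class == "deletion" else "DUP"
            alt = f"<{svtype}>"
            svlen = r.length_bp if svtype == "DUP" else -r.length_bp
            cells = []
            by_id = {g.sample_id: g for g in result.genotypes[i]}
            for s in samples:
                g = by_id[s]
                if g.missing:
                    cells.append("./.:.:.")
                    continue
                gt = gt_map.get(g.copy_number, ".") if svtype == "DEL" else "."
                q = f"{g.quality:.4g}" if g.quality is not None else "."
                cells.append(f"{gt}:{g.copy_number}:{q}")
            fh.write(
                f"{r.chromosome}\t{r.start_bp + 1}\t.\tN\t{alt}\t.\t.\t"
                f"END={r.end_bp};SVTYPE={svtype};SVLEN={svlen}\tGT:CN:GQ\t"
                + "\t".join(cells) + "\n"
            )


# -------------------------------------------------------- callset comparison


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(|a∩b|/|a|, |a∩b|/|b|) for half-open intervals on one chromosome."""
    if a[1] <= a[0] or b[1] <= b[0]:
        raise ValueError("empty interval")
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def _read_bed(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: malformed BED line (<3 columns)")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: non-integer BED coordinates") from e
            out.append((parts[0], start, end))
    return out


def compare_callsets(query_bed, reference_bed, threshold: float = 0.5) -> pd.DataFrame:
    """Match each query interval against a reference callset.

    A query *matches* when some same-chromosome reference interval reaches
    reciprocal overlap >= threshold; ``contains`` counts reference
    intervals fully inside the query (large events tiled by smaller calls
    in the reference are reported this way rather than as matches).
    """
    query = _read_bed(query_bed)
    ref = _read_bed(reference_bed)
    rows = []
    for chrom, qs, qe in query:
        same = [(s, e) for c, s, e in ref if c == chrom]
        matched = any(
            reciprocal_overlap((qs, qe), (s, e)) >= threshold for s, e in same
        )
        contains = sum(1 for s, e in same if qs <= s and e <= qe)
        rows.append(
            {
                "chrom": chrom,
                "start": qs,
                "end": qe,
                "matched": matched,
                "contains": contains,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "matched", "contains"])
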