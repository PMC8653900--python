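"""Synthetic WGS-cohort depth simulator with planted CNVs and a truth set.

The generator emulates the input regime of a population-scale, high-depth
(>18x) WGS call set: biallelic SNV markers with geometric inter-marker gaps
(default mean 1.5 kb), per-sample mean depth around 22x with 10% lognormal
scatter, and per-marker relative depth 0.5*n + N(0, sd) truncated at zero,
where n is the sample's copy number at that position.  Deletion and
duplication events are planted at chosen allele frequencies with genotypes
drawn under Hardy-Weinberg equilibrium.  The cohort can be written as a
minimal sorted VCF with per-sample FORMAT/DP, giving every pipeline stage a
self-contained, deterministic test bed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_depth import MarkerDepthMatrix

_REF_ALT = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]


@dataclass
class CNVEvent:
    """A planted event: half-open interval, type, and allele frequency."""

    start_bp: int
    end_bp: int
    kind: str  # "del" or "dup"
    allele_frequency: float

    def __post_init__(self) -> None:
        if self.kind not in ("del", "dup"):
            raise ValueError("event kind must be 'del' or 'dup'")
        if not (0 < self.allele_frequency < 1):
            raise ValueError("allele frequency must be in (0, 1)")
        if self.end_bp <= self.start_bp:
            raise ValueError("event interval is empty")


@dataclass
class SimulatedCohortSpec:
    """Study conditions for one simulated chromosome.

    Defaults mirror a realistic cohort-WGS regime: ~1.5 kb SNV spacing,
    22x mean depth with 10% per-sample scatter, relative-depth noise sd 0.1.
    """

    n_samples: int = 500
    chrom_length_bp: int = 10_000_000
    marker_spacing_bp: int = 1500
    mean_depth: float = 22.0
    depth_scatter: float = 0.10  # lognormal CV of per-sample mean depth
    noise_sd: float = 0.1
    events: list[CNVEvent] = field(default_factory=list)
    seed: int = 0
    chromosome: str = "1"
    poisson_reads: bool = False  # optional Poisson layer on raw counts
    ar1_noise: float = 0.0  # optional AR(1) coefficient for correlated noise

    def __post_init__(self) -> None:
        ev = sorted(self.events, key=lambda e: e.start_bp)
        for a, b in zip(ev, ev[1:]):
            if b.start_bp < a.end_bp:
                raise ValueError("planted events must not overlap")
        for e in ev:
            if e.start_bp < 0 or e.end_bp > self.chrom_length_bp:
                raise ValueError("event interval outside chromosome")
        self.events = ev


@dataclass
class TruthSet:
    """Planted events with per-sample true copy numbers (events x samples)."""

    events: list[CNVEvent]
    sample_ids: list[str]
    copy_numbers: np.ndarray  # shape (n_events, n_samples), ints

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tstart\tend\ttype\tAF\n")
            for e in self.events:
                fh.write(f"1\t{e.start_bp}\t{e.end_bp}\t{e.kind}\t{e.allele_frequency}\n")


def _hwe_genotypes(rng, n_samples: int, af: float) -> np.ndarray:
    """Number of variant alleles (0/1/2) per sample, two Bernoulli draws."""
    return rng.binomial(1, af, size=n_samples) + rng.binomial(1, af, size=n_samples)


def simulate_cohort(spec: SimulatedCohortSpec) -> tuple[MarkerDepthMatrix, TruthSet]:
    """Draw a cohort depth matrix and its truth set, deterministic in seed."""
    rng = np.random.default_rng(spec.seed)

    # marker positions: geometric gaps with the requested mean spacing
    n_guess = int(spec.chrom_length_bp / spec.marker_spacing_bp * 1.3) + 10
    gaps = rng.geometric(1.0 / spec.marker_spacing_bp, size=n_guess)
    pos = np.cumsum(gaps)
    pos = pos[pos <= spec.chrom_length_bp]
    n_markers = len(pos)

    sample_ids = [f"S{i:04d}" for i in range(spec.n_samples)]
    mean_depth = spec.mean_depth * rng.lognormal(
        -0.5 * np.log1p(spec.depth_scatter**2),
        np.sqrt(np.log1p(spec.depth_scatter**2)),
        size=spec.n_samples,
    )

    # copy-number surface: diploid baseline, events add/subtract alleles
    cn = np.full((n_markers, spec.n_samples), 2, dtype=np.int64)
    truth_cn = np.zeros((len(spec.events), spec.n_samples), dtype=np.int64)
    for k, ev in enumerate(spec.events):
        alleles = _hwe_genotypes(rng, spec.n_samples, ev.allele_frequency)
        delta = -alleles if ev.kind == "del" else alleles
        truth_cn[k] = 2 + delta
        in_ev = (pos > ev.start_bp) & (pos <= ev.end_bp)
        cn[in_ev] += delta[None, :]

    noise = rng.normal(0.0, spec.noise_sd, size=(n_markers, spec.n_samples))
    if spec.ar1_noise:
        phi = spec.ar1_noise
        scale = np.sqrt(1.0 - phi * phi)
        for i in range(1, n_markers):
            noise[i] = phi * noise[i - 1] + scale * noise[i]
    rel = np.maximum(0.5 * cn + noise, 0.0)
    raw = rel * mean_depth[None, :]
    if spec.poisson_reads:
        raw = rng.poisson(raw).astype(np.float64)
    else:
        raw = np.round(raw)

    matrix = MarkerDepthMatrix(
        chromosome=spec.chromosome,
        positions=pos.astype(np.int64),
        sample_ids=sample_ids,
        depth=raw,
    )
    return matrix, TruthSet(spec.events, sample_ids, truth_cn)


def write_synthetic_vcf(matrix: MarkerDepthMatrix, path) -> Path:
    """Write a minimal sorted VCF with per-sample FORMAT/DP.

    Plain text, byte-identical for identical input; REF/ALT cycle through
    fixed SNV pairs.  ``read_vcf_depths`` round-trips it exactly.  Use
    ``pysam.tabix_compress``/``tabix_index`` for a bgzipped, indexed copy.
    """
    path = Path(path)
    chrom = matrix.chromosome
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for i, p in enumerate(matrix.positions):
            ref, alt = _REF_ALT[i % 4]
            cells = []
            for v in matrix.depth[i]:
                cells.append("./.:." if np.isnan(v) else f"0/1:{int(v)}")
            fh.write(
                f"{chrom}\t{int(p)}\t.\t{ref}\t{alt}\t.\t.\t.\tGT:DP\t"
                + "\t".join(cells)
                + "\n"
            )
    return path
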