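import numpy as np
import pytest

from depthcnv import (
    CNVEvent,
    RelativeDepthMatrix,
    SimulatedCohortSpec,
    normalize_relative_depth,
    simulate_cohort,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
)


def write_vcf(path, records, samples=("S1", "S2"), header=VCF_HEADER):
    """Write a small VCF from (pos, ref, alt, format, cells...) tuples."""
    with open(path, "w") as fh:
        fh.write(header)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for pos, ref, alt, fmt, *cells in records:
            fh.write(
                f"1\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\t{fmt}\t" + "\t".join(cells) + "\n"
            )
    return path


@pytest.fixture(scope="session")
def small_cohort():
    """60 samples, 2 Mb, one 200 kb deletion at AF 0.2 (noise sd 0.1)."""
    spec = SimulatedCohortSpec(
        n_samples=60,
        chrom_length_bp=2_000_000,
        events=[CNVEvent(500_000, 700_000, "del", 0.2)],
        seed=1,
    )
    matrix, truth = simulate_cohort(spec)
    return spec, matrix, truth


@pytest.fixture(scope="session")
def small_rdm(small_cohort):
    _, matrix, _ = small_cohort
    return normalize_relative_depth(matrix)


@pytest.fixture
def flat_rdm():
    """Deterministic all-diploid relative-depth matrix, 3 samples."""
    positions = np.arange(1, 301) * 1000
    rel = np.ones((300, 3))
    return RelativeDepthMatrix(
        chromosome="1",
        positions=positions,
        sample_ids=["A", "B", "C"],
        rel_depth=rel,
        chrom_mean_depth=np.array([20.0, 25.0, 30.0]),
    )
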