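# depthcnv

Population-wide germline copy-number variant (CNV) calling and genotyping
from the per-sample depth fields (`FORMAT/DP`) of multi-sample
whole-genome-sequencing VCF call sets.

Most CNV callers reprocess aligned reads, which is expensive at cohort
scale. When an SNV call set already exists, the depth recorded at every
variant site is a free, sparse readout of copy number: over long stretches
the expected *relative* depth of a sample (depth divided by its
chromosome-wide mean) is

    E[d̂(x)] = 0.5·n,        d̂(x) = Σₖ k · 1{d(x)=k}(x) + ε,  ε ~ N(0, σ)

where `n` is the copy number at position `x`. A deletion carrier sits near
0.5 (het) or 0 (hom), a duplication carrier near 1.5 or 2. `depthcnv` mines
this signal for cohorts of hundreds to thousands of samples:

1. **Segment** — per sample, in 10 Mb windows, fit a piecewise-constant
   function to relative depth with a regression tree (complexity 0.01,
   minimum leaf 6 markers; the rpart-style rule that a split must improve
   the model r² by the complexity value). These settings are deliberately
   restrictive: only broad depth changes survive.
2. **Score** — pool segments across all samples and fit a Gaussian mixture
   whose means are fixed at the multiples of 0.5 spanned by the observed
   depth range (EM over weights and per-component sds only). Each segment
   gets the nearest half-integer *ideal depth* and a score `s = 2p`, `p`
   the one-sided tail probability under its component; `s > 0.1` marks a
   high-quality (HQ) segment.
3. **Call** — discretise the window into 5 kb chunks; a chunk supports an
   anomaly when HQ non-diploid segments outnumber low-quality ones (a
   single HQ segment suffices — singleton carriers are called). Run-length
   encoding of supporting chunks yields the CNV regions. A deletion-only
   mode uses only sub-diploid segments.
4. **Genotype** — per sample and region, either the length-weighted mean
   of assigned segment depths (segment-based) or the nearest half-integer
   to the mean marker depth (means-based; robust near the detection
   limit), both rounded to a multiple of 0.5; copy number is twice the
   assigned depth. Genotype QC flags complex or low-confidence calls as
   missing, and a manual genotyper applies means-based genotyping to any
   user-specified interval.

A self-contained cohort simulator (Hardy–Weinberg genotypes at planted
events, Gaussian relative-depth noise, VCF output) makes the whole pipeline
testable without external data.

## Worked example

```sh
depthcnv simulate --out cohort.vcf --truth truth.bed --samples 500 \
    --length 10000000 --seed 7 --event 4000000-4200000:del:0.1
depthcnv call --vcf cohort.vcf --chrom 1 --out run1 --genotyper means
# -> called 1 regions; outputs at run1.*
depthcnv compare --query run1.regions.bed --ref truth.bed --f 0.5
# -> 1/1 queries matched at f>=0.5; 1 contain at least one reference interval
```

`run1.regions.tsv` then contains the called deletion:

```
chrom  start    end      event_class  n_supporting_chunks  edge   deletion_af
1      3995000  4205000  deletion     42                   False  0.102
```

i.e. the planted 200 kb deletion (true allele frequency 0.1) recovered with
both boundaries within one 5 kb chunk and a deletion allele frequency of
0.102 estimated from the per-sample genotypes in `run1.genotypes.tsv`
(copy numbers 0/1/2; `run1.cnv.vcf` carries the same calls as symbolic
`<DEL>` records with GT/CN/GQ per sample).

The same machinery is available as a library, in scikit-learn style:

```python
from depthcnv import CNVCaller, normalize_relative_depth, read_vcf_depths

rdm = normalize_relative_depth(read_vcf_depths("cohort.vcf", "1"))
caller = CNVCaller(genotyper="means").fit(rdm)
caller.regions_            # called CNVRegion list
caller.allele_frequencies_ # deletion AF per region
```

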