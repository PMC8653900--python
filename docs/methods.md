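# Methods

## Depth model

The observed read depth of one sample, normalised by its chromosome-wide
mean depth, is modelled as a noisy piecewise-constant function of genomic
position: relative depth d̂(x) = 0.5·n(x) + ε with n(x) the copy number
and ε ~ N(0, σ). The error term absorbs everything that is not copy
number — GC content, reference quality, mapping bias — which acts on short
ranges, so over the long stretches relevant to large CNVs the per-sample
signal is flat around 0.5·n. Only biallelic SNV sites carry depth
observations; the inter-SNV spacing therefore bounds the achievable
boundary precision. Missing depth entries are excluded from the normaliser
and from every downstream average, never imputed or zero-filled. The
normaliser is the chromosome-wide **mean** over kept markers (computed
after marker filtering); the mean, not the median, matches E[d̂] = 0.5·n,
but a `--norm-stat median` switch exists for heavy-tailed depth
distributions.

## Segmentation

Each sample's windowed signal is fitted by recursive binary splitting on
position, minimising within-piece SSE. A split is accepted only when it
reduces total SSE by at least `complexity × SSE(root)` — the relative-r²
convention of rpart's anova method, applied against the root fit, not the
parent node — and both children must keep at least `min_leaf` markers
(rpart's minbucket; a node below `2·min_leaf` is never split, rpart's
derived minsplit). Growth is restrictive by construction; there is no
grow-large-then-prune pass and no cross-validation. Tie-breaks between
equally good cuts go to the leftmost cut, making the fit deterministic.
Two further numerical details: an additional strictly-positive-gain guard
stops zero-variance nodes from splitting (cp × 0 = 0 would otherwise admit
a no-op split), and the best-cut scan is a vectorised prefix-sum
computation, verified in the tests against a transparent O(n²) greedy
reference and an exhaustive minimal-SSE dynamic programme. Defaults
(complexity 0.01, min_leaf 6) are chosen for cohort-scale data: with >100
samples in a 10 Mb window they only follow broad depth changes. Note that
`min_leaf` constrains where a cut can fall, not whether a short true piece
is representable: a 5-marker terminal drop shifts the cut so both pieces
reach 6 markers, exactly as rpart does.

A consequence of the root-relative rule worth knowing when tuning: the
detectability of an event depends on its SSE contribution *relative to the
whole window*. At noise sd 0.1, a heterozygous 200 kb deletion (~133
markers at 1.5 kb spacing) sits near the single-split acceptance threshold
of a 10 Mb window; homozygous carriers (amplitude 1.0) are comfortably
above it. Lowering `complexity`, or shrinking the window, moves the limit
to smaller events at the cost of false splits.

## Scoring against half-integer states

Fitted segment depths pooled across the population cluster at multiples of
0.5 when anomalies are genuine copy-number states. Per window, a Gaussian
mixture is fitted with means fixed on the half-integer grid spanning the
observed depth range — specifically from the half-integer nearest the
minimum observed depth to the one nearest the maximum (clipped at 0),
which guarantees every segment's nearest state has a component. EM updates
weights and per-component standard deviations only; means never move.
Initialisation is deterministic (uniform weights, sd 0.1); convergence is
a log-likelihood change below 1e-8 or 500 iterations; sds are floored at
0.01 to avoid singularities, and components are never dropped however
small their weight, so every state stays scoreable. Segments enter the fit
unweighted (one vote each, regardless of marker count).

Each segment is assigned the half-integer nearest its fitted depth; exact
quarter-point ties round toward 1.0, the diploid null, because a tie
carries no evidence. Its score is s = 2·(1 − Φ(|fitted − ideal|/sd)),
using the sd of the component at the ideal depth: s = 1 exactly on the
state, decaying with standardised distance; s > 0.1 (strict) defines a
high-quality segment.

## Region calling

Windows are discretised into 5 kb chunks aligned to the window start (a
final partial chunk is kept). A segment is attributed to every chunk it
overlaps at all — the most sensitive attribution. Counting only segments
with ideal depth ≠ 1, a chunk supports an anomaly when HQ/LQ >
`ratio_threshold` (default 1), with the convention that zero LQ segments
plus at least one HQ segment supports — so a single high-quality carrier
is enough to call a singleton variant. Maximal runs of supporting chunks
(run-length encoding) become regions, classed deletion/duplication/mixed
by the ideal depths of the HQ segments they contain. Regions touching a
window edge are flagged and merged across windows when two flagged regions
in adjacent windows lie within one chunk of each other. Deletion-only mode
filters to sub-diploid segments before voting; note that removing LQ
duplication segments can lift a chunk over the ratio threshold, so
deletion-only output is not a strict subset of default-mode regions on
adversarial inputs, though it is on realistic cohorts. Windows in which
every fitted segment lies within 0.15 of diploid skip the mixture fit and
return no regions — on such windows every ideal depth would be 1.0, so the
shortcut is result-identical.

## Genotyping

Segment-based: the mean of a sample's assigned segment depths over the
region, weighted by the bp length of each segment *clipped to the region*
(so a long diploid flank cannot swamp the event), rounded to the nearest
half-integer (same diploid tie rule); quality is the length-weighted mean
segment score. Means-based: the half-integer nearest the sample's mean
marker relative depth across the region; quality is the distance between
mean and assigned depth. Copy number is twice the assigned depth, capped
at the largest mixture state observed. Segment-based genotyping is biased
toward the reference for events near the detection limit — carriers whose
individual regression missed the event inherit a diploid segment — while
means-based genotyping is agnostic to how the region was found; the two
agree on large, clean events. The pipeline default is segment-based
(`genotyper="segment"`); quantitative recovery checks use means-based for
this reason. Genotype QC sets a call to missing when it has more than 4
segments, a segment-based aggregate score below 0.1, or a means-based
distance above 0.2; the criteria are standard, the threshold values are
this package's defaults and are exposed in the config. Deletion allele
frequency is (2·n_CN0 + n_CN1)/(2·n_genotyped) over non-missing samples.

## Synthetic cohorts

The simulator draws marker positions with geometric gaps (default mean
1.5 kb, the SNV density of high-depth WGS call sets), per-sample mean
depth lognormal around 22x with 10% scatter, HWE genotypes at each planted
event, and relative depth 0.5·n + N(0, noise_sd) truncated at zero
(default sd 0.1); raw depth is the rounded product with the sample's mean
depth. Noise is applied on the relative-depth scale — exactly the model's
ε — with optional Poisson resampling of raw counts and optional AR(1)
noise correlation for stress-testing the ratio knob. It does **not**
emulate GC waves, mappability dropouts, segmental-duplication
cross-mapping, batch effects, or reference errors; passing tests therefore
demonstrate correctness of the algorithm under its own model, not
performance on adversarial genomic regions (real call sets still need the
manual QC the diagnostics support).

## Problem sizes and checks

Tests and the acceptance script run at the regime the method targets: 500
samples, one 10 Mb chromosome at ~1.5 kb marker spacing (≈6,600 markers),
a 200 kb deletion at allele frequency 0.1 — sizes at which the whole
pipeline completes in seconds while exercising every code path at
realistic density. Under these conditions the planted deletion is
recovered with boundaries within 1–3 chunks (5–15 kb, consistent with the
~10 kb precision limit set by leaf size and chunk width), means-based
non-reference genotype concordance of 100%, allele-frequency error ≤0.005,
zero false-positive regions over ten event-free 10 Mb cohorts, and ≥99%
agreement between the two genotypers on low-noise (sd 0.05) cohorts.
Segmentation is validated against rpart semantics (cross-checked against
the R implementation during development) via two independent oracles, and
the constrained EM recovers mixing weights to within 0.05 on 1,000-segment
draws.

## Known limitations

Boundary precision is chunk-width plus marker-spacing limited; no
read-level breakpoint refinement. Small (<~100 kb at default settings) or
rare events depend on at least one carrier producing a clean regressed
segment. Duplications show more complex depth behaviour than deletions and
are not GT-genotyped in the VCF output (CN only). No association testing,
LD computation, kinship, or annotation against external variant databases
is included.
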