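# Methods

## Coordinate and data conventions

All internal coordinates are 1-based inclusive (length = end − start + 1),
the convention of the rawcnv call dialect the pipeline consumes; BED files
are converted at the I/O boundary (start + 1 on read) and the conversion is
an exact bijection. Chromosome labels are normalised by stripping a leading
`chr`. Missing LRR/BAF values are explicit NaNs: they are excluded from QC
statistics and skipped in the HMM emission rather than treated as zero,
which would bias SD(LRR) downward and distort the BAF mixture.

## Quality control

Sample metrics: call rate (fraction of non-missing genotype calls), SD of
non-missing autosomal LRR, BAF drift (fraction of BAFs in the artifact bands
[0.20, 0.25] ∪ [0.75, 0.80] — the conventional definition of this metric;
only the 0.01 threshold is standard), and a waviness factor defined here as
the SD of per-1-Mb-window median LRR. The usual GC-correlated waviness
definition needs a GC track; the window-median form captures the same
long-range intensity waves with no external data, and is the deliberate
design choice of this package. Thresholds: call rate ≥ 0.90, SD(LRR) < 0.30,
BAF drift < 0.01, waviness < 0.05.

Marker metrics: missingness ≤ 0.10, MAF ≥ 0.05, and a Hardy–Weinberg
chi-square goodness-of-fit test (1 df; monomorphic markers are defined to
have P = 1). The "multiple-test-adjusted P < 10⁻⁵" rule is implemented as
Bonferroni: a marker fails when its raw P < 10⁻⁵ / n_markers. Identity-by-
descent screening is out of scope; callers can drop samples from the cohort
list directly.

PFB (population frequency of the B allele) is the per-marker mean of
non-missing BAF, clamped to [0.01, 0.99]; an all-missing marker falls back
to 0.5 with a warning.

## The copy-number HMM

Five hidden states, one per copy number 0–4. The copy-neutral LOH state of
some callers is omitted: only losses and gains are analysed downstream.

**Emission.** The LRR term is Gaussian at the state mean with per-state SD.
Default means μ = {0: −3.5, 1: −0.66, 2: 0, 3: +0.40, 4: +0.68} are the
canonical Illumina-array values. The BAF term is a mixture over the genotype
clusters a state allows: for copy number c > 0, clusters sit at b/c for
B-allele dosage b = 0..c with Binomial(c, PFB) weights; clusters at 0 and 1
are half-Gaussians (folded at the boundary, so each integrates to 1); cn = 0
has no genotype and emits uniform density 1 on [0, 1]. With the default
cluster SD (0.05) each state's mixture integrates to 1 within 10⁻⁶ over
[0, 1]; the interior-cluster truncation error grows if the SD is pushed far
above ~0.1. Default emission SDs (LRR 0.25, BAF 0.05) are set slightly wider
than typical array noise so decoding tolerates real-data dispersion.

**Transition.** P(stay) = 1 − (1 − p_stay)(1 − e^(−d/d₀)) with p_stay =
0.999 and d₀ = 100 kb: adjacent markers almost never switch state, while
markers far apart approach the baseline switch rate. Off-diagonal mass is
split uniformly over the other four states. This captures the distance
dependence of the classic caller without its unpublished fitted matrix.

**Decoding.** Viterbi in log space per chromosome (deterministic, testable
boundaries; no forward–backward posterior masking). Maximal non-diploid runs
of ≥ min_snps (default 3) markers become calls with boundaries at the run's
first/last marker positions; shorter runs are absorbed into the diploid
background. Start probabilities put 0.99 on the diploid state. Finiteness of
the decoded score is asserted, so underflow on very long chromosomes cannot
pass silently.

## CNVR merging and summaries

Merging is single-linkage: intervals join when they overlap by ≥ 1 bp and
the union is transitive, so a region can span call pairs that never directly
overlap each other (the convention of the region-construction literature
this follows). The 1-kb minimum length applies to the *merged* regions, not
to input calls. Frequency uses the post-QC cohort size as denominator and
counts each carrier animal once, however many of its CNVs fall in the
region; a 48-animal cohort therefore has a frequency floor of 100/48 ≈ 2.1%.
Summaries: per-chromosome count, total length, coverage, inter-region
spacing (next.start − current.end − 1, undefined below 2 regions), a length
histogram over the bins (<10, 10–50, 50–100, 100–500, 500–1000, >1000 kb),
and an OLS regression of per-chromosome region count on chromosome length
with its R².

## Cross-study comparison

All comparisons use the same ≥ 1 bp overlap rule (no reciprocal-overlap
requirement; a reciprocity threshold would be a caller-level option, off by
default). A query region is *known* when it overlaps any region of any
reference study. The composite set is the union-merge of all studies'
regions; the binary presence matrix marks which studies hit each composite
region. PCA operates on row-centered (not scaled — the data are binary)
presence rows via SVD; scores are U·S, eigenvalues S²/(n_regions − 1).
Clustering is average linkage on Jaccard distance between presence rows,
serialisable as Newick. The distance/linkage pair is a design choice of this
package: Jaccard is the natural distance for binary incidence data and
average linkage avoids single-linkage chaining. Breed-specific detection
filters regions < 100 kb, re-merges within each dataset, and keeps regions
overlapping no other dataset; Venn counts are taken over the composite of
the filtered regions, each composite region counted once.

## Annotation and enrichment

Genic/intergenic and QTL tallies use ≥ 1 bp overlap via interval trees. Gap
overlap ignores gaps < 1 kb and reports both the number of calls touching a
gap and the number of distinct gaps touched. Enrichment is a hypergeometric
upper tail per gene set with Benjamini–Hochberg correction across sets; the
universe defaults to the supplied annotation's genes (configurable) — a
deliberate, documented choice since web-service enrichment backgrounds vary.
The modified-Fisher statistics of annotation web services are intentionally
not replicated, so enrichment P-values are comparable only within this tool.

## qPCR arithmetic

ΔΔCT = (CT_target,test − CT_ref,test) − (CT_target,cal − CT_ref,cal) with
replicates averaged first; fold change 2^(−ΔΔCT); NR = 2·2^(−ΔΔCT).
Status thresholds 0.5 / 1.5 / 2.5 are the midpoints between the integer-copy
ratios 0, 1, 2, 3. Amplification efficiency is fixed at perfect doubling. A
fully deleted target never amplifies; simulations cap its CT at a 40-cycle
ceiling, which maps to NR ≈ 0 as required. When several calibrator samples
are available their CTs are passed as replicates and averaged.

## Synthetic data: what it emulates, and what it does not

The generator is the package's test bed and defines its study conditions.
Defaults: 48 samples; five autosomes totalling 75 Mb (a scaled-down genome —
full 26-autosome, 2.6-Gb simulation adds nothing to correctness testing);
230 markers/Mb (a 600K-probe array over 2.6 Gb); 0.042 CNVs per sample per
Mb (≈ 5,200 events per 48-sample cohort per 2.6 Gb); CNV lengths log-uniform
on 50–300 kb, the floor chosen so every event spans ≥ 10 markers at the
default density; loss:gain odds 10 (the loss excess array studies report),
with losses split 9:1 between cn 1 and 0 and gains 9:1 between cn 3 and 4;
LRR noise SD 0.2; BAF cluster SD 0.03; PFB ~ Beta(0.7, 0.7) clamped to
[0.01, 0.99]. Artifact knobs (BAF drift contamination, sinusoidal LRR
waviness, genotype missingness) default to off/low and are switched on
explicitly where the QC filters are exercised. All randomness flows through
numpy's `default_rng` (PCG64) seeded from `SimulationConfig.seed`, giving
bit-identical output across platforms.

Not emulated: linkage disequilibrium between genotypes, GC-content waves
correlated with real sequence, probe-specific biases, sex chromosomes, or
overlapping CNVs within one sample (placement rejects overlaps so the truth
stays unambiguous for precision/recall). Consequently a passing test suite
demonstrates the *pipeline's* correctness and the HMM's statistical power
under honest noise, not calling accuracy on any particular real array.
Because the CNV load of a realistic cohort is concentrated on a 75-Mb
genome, aggregate figures that scale with genome size (e.g. percent genome
coverage by CNVRs) come out far higher than on a full genome, and samples
carrying a large homozygous deletion can legitimately trip the SD(LRR)
filter; both are scale effects, not defects.

## Numerical and degenerate-input choices

Log-space arithmetic throughout the HMM; mixture densities floored at
1e-300 before the log. Monomorphic HWE P = 1; all-missing PFB = 0.5 with a
warning; chromosomes with fewer markers than min_snps produce no calls with
a warning; empty study tables read as empty datasets; zero-variance presence
matrices and concordance vectors raise instead of returning NaN. Ties in
Viterbi resolve to the lower copy number (numpy argmax takes the first
maximum), a stable, documented tie-break.

## Problem sizes used in the shipped analyses and tests

The analysis drivers use the default 48-sample cohort (~17,250 markers,
~140 CNVs). The recovery tests use 20 samples at LRR SD 0.2 with a fixed
seed; oracle-equivalence tests use ≥ 100 randomized instances on ≤ 1-Mb toy
chromosomes; statistical oracles run on small closed-form instances at 1e-8
relative tolerance. These sizes are the package's own choice of a compact,
fully reproducible test bed.
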