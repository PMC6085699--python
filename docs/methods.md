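# Methods

## Problem and approach

Two tumours from one patient are either clonally related (descended from
one transformed progenitor, hence sharing its early driver events) or
independent primaries (sharing only what recurs in the population or
coincides by chance). Every test in this package operationalises that
dichotomy the same way: measure a similarity statistic on the true pair
and locate it in the distribution of the same statistic over all
artificial cross-patient pairs of the cohort. Artificial pairs share the
population-recurrent component and measurement coincidence but cannot
share patient-specific clonal events, so they estimate the null.

For *n* patients with two tumours each there are *n* true pairs and
2*n*(*n*−1) unordered artificial pairs (together exhausting the C(2*n*, 2)
sample pairs). Artificial-pair distributions are computed exhaustively —
cohorts of this size make that cheap — and are shared by all true pairs of
a cohort/platform, which makes within-cohort decisions correlated (see
*Calibration* below).

## Discretization

Copy-number log2 ratios (aCGH, methylation-derived intensities, SNP log R
ratios): heterozygous loss below −0.3, low-level gain above +0.3, both
strict; a value exactly at a threshold is neutral. Expression log2 ratios:
±0.58 (a 1.5-fold change), strict. Methylation beta values: methylated
above 0.8, unmethylated below 0.2, the closed interval [0.2, 0.8]
hemi-methylated. Strictness matters only for values exactly at a
threshold; it is fixed here so results are reproducible to the decimal.

## The similarity-index family

SI = N_S / (N_S + N_U + N_O) over the common probes of a pair, where a
probe contributes to N_S when both tumours carry the same non-neutral
call, N_U when exactly one is aberrant, N_O when both are aberrant in
opposite directions. Probes neutral in both tumours are uninformative: two
genomes agreeing on "no aberration" is not evidence of shared ancestry.
When no probe is aberrant in either tumour the SI is undefined and the
pair is reported not evaluable (rather than silently 0 or 1).

SI_met is the fraction of probes with identical three-level methylation
state, *including* joint hemi-methylated states — methylation has no
single biologically neutral level, so all agreements count.

### The permutation percentage P_SI

P_SI is described in the clonality literature only verbally — the
percentage of a pair's similarity not due to recurrent chromosomal
aberrations or randomness — with the formula living in software that is
not part of this package's sources. We therefore reconstruct it as

    P_SI = max(0, 100 · (SI_obs − mean(SI_null)) / SI_obs),

with SI_null over all artificial pairs: the excess of the observed SI
over its null expectation, as a percentage of the observed SI, floored at
0 for pairs no more similar than a random cross-patient pair. One
cohort-wide null mean per platform reproduces previously reported
SI-to-P_SI mappings within rounding, which is what motivated this
reconstruction; it is flagged as such here because the original scheme
cannot be verified from its verbal description alone. P_SI should be read
as a descriptive effect size — the fraction of observed
similarity in excess of the null expectation — not a significance level.
Significance is carried by the separate empirical p-value
(1 + #{null ≥ obs}) / (1 + N), with the add-one pseudo-count so p is never
exactly 0; clonal is called at p ≤ α, default α = 0.05.

## Distance, clustering, segments, mutations, fusions

* **Distance**: Euclidean distance over common probes; clonal iff the
  true-pair distance is *at or below* the 5th percentile of the
  artificial distances (percentiles via linear interpolation).
* **Clustering**: single linkage on the Euclidean distance matrix; a true
  pair is clonal iff it forms a *cherry* — its two samples merge with each
  other before either merges with anything else. Under single linkage this
  is equivalent to the pair being mutual nearest neighbours strictly
  closer to each other than to any third sample, which the test suite uses
  as an independent oracle. Samples are sorted lexicographically before
  linkage so merge order under ties — and hence the dendrogram — is
  reproducible. A pair merging at the same height as a third sample in one
  node is not a cherry.
* **Shared segments**: segments identical in chromosome, start, end *and*
  aberration direction, normal segments never counted; clonal iff the
  count is *strictly above* the artificial 95th percentile (the wording
  asymmetry — "at or below" for distance, "above" for counts — is
  preserved deliberately). An optional breakpoint tolerance (default 0 bp)
  exists because exact-locus matching across platforms with different
  probe grids is otherwise impossible; the default preserves the exact
  rule.
* **Shared mutations**: |intersection| on (chrom, pos, ref, alt),
  optionally after restricting both sets to user-supplied panel regions
  (the breast-cancer/DNA-repair panel itself is not redistributable and
  must be provided; the simulator fabricates a stand-in). Same strict
  95th-percentile rule.
* **Fusions**: count of transcripts with identical 5′ and 3′ partner
  breakpoints; gene symbols are reported but never used as the match key.
  Scored against the artificial null like the other counts; in realistic
  cohorts the null is almost surely all-zero, so any shared fusion is
  called clonal.

## Aggregation

Cohen's κ = (p_o − p_e)/(1 − p_e), unweighted, on the two informative
categories; not-evaluable calls are dropped pairwise — the least
committal missing-data choice. κ is undefined (NaN) when fewer than two jointly
evaluable patients remain or both raters are constant (p_e = 1). Methods
are ranked by mean κ against all others; per-patient consensus is the
count of clonal votes over evaluable methods. The copy-number SI is
designated the primary classification in summaries — it is the most
interpretable statistic, purpose-built for clonality, and consistently
among the most concordant with the rest — with every other method
reported alongside.

## Synthetic cohorts

The generator emulates what the tests assume, with defaults chosen to
resemble a breast-cancer aCGH cohort:

* **Genome**: 22 autosomes carrying `n_probes` (default 500) probes split
  into candidate segment blocks of `probes_per_block` (default 5) probes.
  Events occupy whole blocks, so an event present in two tumours has
  identical breakpoints — mirroring segmentation on a shared probe grid,
  the regime in which exact-breakpoint matching is meaningful.
* **Hotspots**: ten recurrent regions (gains 1q, 8q, 16p, 17q, 20q;
  losses 1p, 8p, 11q, 13q, 16q) at population frequencies 0.25–0.40,
  drawn once per patient for clonal pairs (founder events) and per tumour
  for independent ones — so independent pairs share hotspots only at
  frequency².
* **Clonal structure**: clonal patients draw `n_founder_events` (default
  8) founder blocks shared by both tumours; every tumour adds
  `n_drift_events` (default 3) private subclonal blocks. Independent
  patients draw the same total burden privately. Segment effects are
  ±0.6 on the log2 scale — safely beyond the ±0.3 thresholds — with
  per-probe Gaussian noise `noise_sd` (default 0.10; 0.05 is the
  strong-signal condition used in recovery experiments).
* **Methylation**: a bimodal CpG landscape on the logit-beta scale;
  clonal pairs share a per-probe patient deviation (SD 1.5), each tumour
  adds logit noise (SD 0.5). Expression follows the same
  shared-vs-private latent pattern on the log2 scale.
* **Variants**: each tumour carries `n_variants` (default 30) somatic
  variants — a fraction `variant_share_rate_clonal` (default 0.7) of them
  founder-shared in clonal pairs — on top of a residual
  population-polymorphism background: 5000 sites with Beta(0.5, 2.5)
  frequencies, carried independently per tumour. The background models
  sequencing-derived variant lists after imperfect germline filtering,
  which is what makes cross-patient sharing common and the permutation
  null informative. Treating the background as independent between a
  patient's two tumours is a deliberate simplification (real pairs share
  a germline); it matches the exchangeability the permutation null
  assumes and keeps zero-signal cohorts genuinely null.
* **Fusions**: breakpoints drawn from a space large enough that
  cross-patient collisions essentially never occur; clonal pairs share
  exactly `fusion_share_count_clonal` (default 5) fusions by
  construction.
* **Clinical records**: feature concordance is tied loosely to ground
  truth (clonal pairs concordant per feature with probability 0.95).
  This exercises the clinical module; in real cohorts clinical
  concordance associates poorly with molecular clonality, so clinical
  agreement should never be read as molecular evidence.

Randomness: one seed drives a `SeedSequence` whose children seed the
cohort-level landscape and one stream per patient, so output is
bit-identical under a fixed config and per-patient draws are stable.

What the generator does **not** emulate: intratumour heterogeneity and
subclonal fractions, normal-cell contamination, probe-specific noise and
GC waves, chromosome-arm correlation structure, germline sharing within a
patient, realistic variant allele frequencies. Passing recovery tests on
these cohorts demonstrates the statistical machinery is correct under the
assumed structure, not clinical performance on real arrays.

## Calibration and numerical notes

On zero-signal cohorts (no clonal patients) every tumour is exchangeable,
so each test's rejection rate estimates its attained false-positive level.
Monte-Carlo bands use the between-cohort standard error, because the 20
decisions within a cohort share one artificial-pair null and are
correlated. Measured over 500 cohorts (20 patients × 500 probes):

* distance and SI empirical-p reject at ≈ 0.048–0.05 — nominal;
* shared mutations ≈ 0.043 and shared segments ≈ 0.025 — *conservative*.

The conservativeness is intrinsic, not a bug: for an integer-valued count
compared *strictly above* an empirical 95th percentile, the attained level
is 1 − F(k) for the threshold count k with F(k) ≥ 0.95, i.e. short of 5%
by up to the probability atom at k. Shared-segment counts take a handful
of values (atom ≈ 0.02–0.03); shared-mutation counts, inflated by the
polymorphism background into the hundreds, are nearly continuous (atom
≈ 0.005–0.01). Users comparing count-based calls against the continuous
tests should expect the former to under-call clonality near the boundary.

Other numerical choices: percentiles use linear interpolation throughout;
permutation nulls need at least 20 artificial pairs or the test returns
not evaluable; pair operations align profiles on the intersection of
probe ids and error below 2 common probes; coordinates are 1-based
inclusive; chromosome names are normalised by stripping `chr`. Sizes used
by the shipped experiments — 500 zero-signal cohorts for calibration, 50
strong-signal seeds for recovery, 200 random cohorts for the clustering
oracle — were chosen to put Monte-Carlo error well below the effect sizes
being checked while keeping a full test run in minutes on one CPU.

## Scope

Out of scope by design: array normalisation and segmentation (inputs are
taken as already normalised/segmented), likelihood-ratio clonality models
from external packages, TCGA-frequency-weighted mutation tests,
ordination (PCA/MDS), and clinical association testing beyond descriptive
concordance counts.
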