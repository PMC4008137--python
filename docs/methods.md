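# Methods

## The generative model

The synthetic compendium emulates a curated, RMA-like microarray tissue
atlas for human, mouse and rat.  For gene *g* in sample *s* of tissue *t*:

    x = mu_g + T[g, t] + P[g, e] * 1[s perturbed in experiment e] + eps

* `mu_g ~ Normal(8, 2^2)` — per-gene log2 baseline, chosen to resemble
  RMA-normalized intensities.
* `T[g, ·]` — tissue-effect vector, entries with standard deviation
  `tissue_effect_sd` (default 2.0 log2 units).  For each ortholog cluster
  the three species' vectors are drawn jointly normal per tissue with an
  exchangeable cross-species correlation `rho` per species pair
  (defaults: mouse–rat 0.9, human–mouse = human–rat 0.6).  This is the
  simplest generative structure that makes "rodents are more conserved
  with each other than with human" a single dial per pair.
* `P[g, e] ~ Normal(0, perturbation_effect_sd^2)` — per-experiment
  perturbation effect, independent across species (real perturbation
  compendia are not comparable across species).  The default
  `perturbation_effect_sd = 2/sqrt(10)` encodes a 10× tissue-to-perturbation
  variance ratio.
* `eps ~ Normal(0, noise_sd^2)` — per-sample noise, default 0.5.

Structural features layered on top:

* **Anti-correlated clusters.**  A fraction `negative_frac` (default 0.05)
  of clusters has the *human* tissue-effect vector negated, yielding the
  minority of negatively correlated orthologs seen in correlation
  histograms.
* **Dominant tissue group.**  A fraction of clusters (default 0.2) carries
  a shared additive offset (default +3 log2) in all CNS tissues, in every
  species.  This is what makes PC1 separate the CNS block from the rest and
  what the architecture-recovery tests recover.
* **Cell-culture signature.**  `cellculture_signature_size` 1:1:1 clusters
  (default 177) have zero tissue effect everywhere except a +4 log2 offset
  in the `cell_culture` category.  The +4 is a free parameter, not an
  estimate — only the filtering outcome is specified by the analysis, so
  the magnitude was fixed once at a value well clear of tissue-effect noise.
* **Probe model.**  Every gene gets one `_at` probe; 0–2 extra probes draw
  suffixes from the multi-target set (`_x_at`, `_g_at`, `_f_at`, `_r_at`,
  `_b_at`, `_l_at`, `_i_at`) plus `_s_at` with weight 0.3.  Including
  `_s_at` among the extras is deliberate: with multi-target extras only,
  suffix filtering would always reduce a gene to a single candidate and the
  present-call selection rule would never be exercised.  Present calls are
  Uniform(0, 100); probe-level noise is Normal(0, 0.2^2).
* **Platform sets.**  The gene-level biology is a deterministic function of
  the seed and shared between SET1 and SET2; samples, noise, probe
  complements and present calls are redrawn per set.  The two sets
  therefore behave as independent measurements of the same regulation,
  which is exactly what the both-sets conjunction rules assume.

All randomness flows from `GeneratorConfig.seed` through named
`SeedSequence` streams, so identical config + seed reproduces byte-identical
output (the pipeline manifest checksums are the regression test for this).

What the generator does **not** model: array-level artifacts, batch
effects, probe-level (CEL) data, inter-experiment scaling, non-normal
expression distributions, and correlated perturbation responses across
species.  Passing tests therefore demonstrate correctness of the analysis
machinery under the stated statistical structure, not robustness to the
full messiness of public microarray repositories.

## Preparation rules

* Suffix matching is longest-first (`_s_at` itself ends in `_at`); only
  `_at` and `_s_at` survive.  Unrecognized suffixes drop the record with a
  warning rather than aborting.
* Present-call ties are broken by lexicographically smallest probe id —
  the selection must be deterministic and no other rule is implied.
* Meta-profiles average **all** samples of a tissue category, including
  perturbation and control samples, on the log2 scale.
* Standardization uses the sample standard deviation (ddof = 1); constant
  rows become all-zero and are flagged rather than dropped.
* Tissue log-ratios subtract the unweighted mean over tissue *categories*
  (not over samples), and `cell_culture` is included in that mean — no
  category exclusion is applied anywhere.
* The strict 1:1:1 subset is decided on cluster composition before probe
  loss: a 2:1:1 cluster that loses a duplicate to filtering does not
  silently re-enter the 1:1:1 analyses.

## Numerical and design choices

* **PCA** is run on tissues × genes (tissues are the observations), column
  centered, no scaling beyond the per-gene standardization already applied.
  Component signs are fixed by forcing each component's largest-magnitude
  loading positive.  PCA is per species; joint display is an export
  concern.
* **Network discretization** uses strict `r > threshold`; the diagonal is
  excluded from degrees (an `include_self` flag restores the
  every-degree-plus-one variant).  Constant genes have undefined
  correlations and are excluded from the node set with a logged count.
* **Range averaging** evaluates every threshold at 0.01 increments within
  a closed range (five thresholds for the canonical ranges) and averages
  P(k) over the union of observed degrees.
* **Power-law fits**: `loglog` is a least-squares slope on
  (log k, log P(k)); `mle` maximizes the zeta-distribution likelihood with
  Hurwitz-zeta normalization at `k_min` (default: smallest positive
  observed degree; configurable).  The degree sampler truncates the support
  at k = 100000, whose tail mass (~1e-10 at exponent 3) is negligible for
  estimation.
* **Enrichment** keeps raw p-values by default (boundary rule `p <= alpha`;
  conventional alphas 0.001 for the positively and 0.05 for the negatively
  correlated set); Benjamini–Hochberg is available but off, for fidelity to
  the raw-cutoff convention.  The odds ratio uses the 2×2 table with an
  infinite sentinel when the term is fully contained in the study set.
* **Best-pair matching** is greedy by rank (deterministic, mirrors the
  "best pair" reading); a Hungarian-style optimal-sum matching is available
  behind `method="optimal"`.  The documented divergence case
  `[[0.9, 0.8], [0.85, 0.1]]` (greedy total 1.0 vs optimal 1.65) is a unit
  test.
* All m_A × m_B pairs are ranked (≤ 16 under the four-per-species cap);
  exports aimed at rank-profile plots truncate at rank 10.
* **Exceedance tie rule** in the variance summary: strictly greater than
  the median tissue variance counts as exceeding.
* The pipeline's enrichment study sets use, per platform set, the mean
  ortholog correlation across the three species pairs; per-pair selection
  remains available through `select_correlated_genes` directly.
* The 177-gene-style category filter is applied to tissue log-ratio
  matrices with thresholds in log2-ratio units (defaults on = 2.0,
  off = 1.0): the spike is defined relative to a gene's own tissue mean,
  so log-ratios are the scale on which "high here, minimal everywhere
  else" is well posed.

## Problem sizes used by the test suite

Simulation-backed checks run at sizes where the statistical claims are
stable across seeds while the whole suite stays fast: conservation-ordering
and recovery tests use 2,000 clusters × 30 tissues (20 seeds);
variance-ratio recovery uses 2,000 genes with 50 tissue and 50 perturbation
categories at reduced noise (sd 0.1) so the generative ratio, not the noise
floor, is measured; architecture recovery uses 500 clusters × 20 tissues
(20 seeds); rank-profile recovery uses 150 all-duplicated clusters; the
exact-recovery test of the cell-culture filter uses 2,000 clusters ×
56 tissues with 10 samples per tissue, where both thresholds sit more than
six standard errors from the nearest failure mode.

## Known limitations

* The generator's co-expression networks are not themselves scale-free by
  construction; power-law estimation is validated against exact power laws
  and sampled degree sequences, not against emergent network topology.
* Sequence-similarity scores are synthetic inputs (clearly labelled as
  such); no alignment is performed.
* GO terms are flat gene sets; DAG ancestor propagation, if wanted, must
  happen upstream of the mapping file.
* With default noise, the measured tissue/perturbation variance ratio sits
  below the generative 10× because perturbation log-ratios carry two
  sample-mean noise terms; the ratio converges to the generative value as
  `noise_sd -> 0` (this is the quantity the recovery test controls).
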