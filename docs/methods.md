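# Methods

## The statistical model

Every association test in the package is one logistic regression contract.
For the case–control burden test of gene *g*:

    logit P(sample is a case) = β₀ + β₁·carrier_g + Σⱼ βⱼ₊₁·PCⱼ

`carrier_g` is the 0/1 indicator "carries at least one qualifying
pathogenic variant in *g*" — carriage collapses over variants and ignores
zygosity, so a sample with two qualifying variants in one gene counts once.
The covariates are the first k = 4 principal components of the
common-variant genotype matrix. β₁ is the natural-log odds ratio; results
report Log2(OR) = β₁/ln 2, its Wald standard error and two-sided p-value.
The two-hit test is the identical contract on cancer samples only, with
LOH status (minor copy number = 0) as the outcome and PCs computed on the
cancer samples alone; the set-level test is the identical contract with
the indicator pooled over a gene set's members ("carries a qualifying
variant in any member gene"). The three tests share one fitting core,
which the suite verifies by relabelling inputs.

With no covariates the MLE equals the crude 2×2 log odds ratio
ln(ad/bc); the implementation exploits this only for speed (observations
collapse onto the four (outcome, carrier) cells with frequency weights,
leaving the estimate unchanged), never for the estimate itself.

### Separation and non-convergence

When a 2×2 cell is empty, or the unpenalized fit diverges (|β₁| > 15) or
fails to converge, the result is flagged (`separation_flag`,
`converged=False`) and the reported estimate comes from a Jeffreys-prior
(Firth) penalized refit — Newton iterations on the penalized score
U*(β) = Xᵀ(y − p + h(½ − p)) with h the logistic hat-matrix diagonal.
Penalized estimates are always finite and marked `penalized=True`; genes
are never silently dropped. Firth regression is implemented in the package
because no installed library provides it.

### Multiplicity and eligibility

Benjamini–Hochberg step-up (via statsmodels) runs over the eligible genes
of one analysis (pan-cancer, or one cancer type); the default significance
threshold is q < 0.20. Eligibility keeps tests out of the family that
cannot be informative: at least 3 total carriers pan-cancer, and strict
per-cancer minima for single-cancer runs (more than 2 for CNS-Medullo and
Liver-HCC, more than 3 for Kidney-RCC, Lymph-BNHL, Ovary-AdenoCA,
Panc-AdenoCA, Prost-AdenoCA and Skin-Melanoma, more than 4 for
Breast-AdenoCA). The same threshold table can be applied to the two-hit
analysis (more than N carriers in either the LOH or no-LOH group) via
`run_twohit(min_group_carriers=...)`; whether those minima belong to the
case–control analysis, the two-hit analysis or both is genuinely ambiguous
in the source material, so both uses are supported and neither is the
default. Single-cancer runs restrict cases and controls to the cancer
type's majority population and refuse to run below 50 cases (configurable),
since a small, ancestry-skewed case set against the full control panel is
exactly the situation PC adjustment cannot rescue.

### Variant classification choices

- MAF rarity uses strict `<` at 0.5% (a 0.1% alternative is a flag for
  sensitivity analysis); cohort detection frequency excludes at strict
  `>` 1%. Subpopulations with no annotated frequency pass — only observed
  frequencies are tested.
- `spliceai_loss_score` is the maximum of the donor-loss and acceptor-loss
  deltas; the PTV threshold (score > 0.8) is strict.
- Terminal-exon and functional-domain status are consumed as boolean input
  annotations; recomputing them from transcript models or domain databases
  is out of scope.
- Classification is a pure function of the variant record: no order
  dependence, verified by property test.

### PCA conventions

Dosages are mean-imputed per variant, centered, scaled to unit variance
and decomposed by thin SVD. Zero-variance variants are dropped with a log
message. Each component's sign is fixed so its largest-magnitude loading
is positive — regression is sign-invariant, but fixtures and reruns need
byte-stable scores. Common variants are selected at MAF ≥ 5% (global and
per annotated group), call rate ≥ 90%, non-synonymous by default. The
non-synonymous restriction is unusual (genome-wide LD-pruned SNPs are more
common) but is the convention this pipeline standardizes on; it is a flag
(`require_nonsynonymous=False`) for users who prefer the usual practice.

### Gene classification

The three features (two-hit Log2OR, TAU ∈ [0,1], LOEUF > 0) live on
incomparable scales, so they are z-standardized before PCA; clustering
runs on all PC scores (full rank — with three features the rotation is
loss-free, so the subset question is moot). "Enhanced" k-means is realized
as 25 random restarts keeping the lowest within-cluster sum of squares at
fixed k = 4; automatic k selection is deliberately not the default because
the four-group structure is part of the method's definition. Cluster
names are attached by median rules — lowest median TAU → broadly
expressed; highest remaining median two-hit Log2OR → canonical two-hit;
the two remaining tissue-specific clusters split by median LOEUF (higher →
pLoF-tolerant). Ties break by LOEUF then two-hit Log2OR. The narrative
labels only make sense for k = 4; other k values return unlabelled
clusters with a notice.

### Transcriptional score

TS = Σ |r| over unordered panel-gene pairs (pairwise mode, the default) or
over anchor–gene pairs (anchor mode); both readings of "absolute sum of
correlation coefficients" are first-class because the phrase is ambiguous.
Pearson correlation is used (not Spearman); zero-variance genes contribute
zero and are logged. The null resamples `subsample_size` (default 45)
columns without replacement from the comparison group `n_resample`
(default 1,000) times; the empirical p-value uses the add-one correction
(1 + #{null ≥ observed})/(n_resample + 1), so it is never exactly zero and
its floor is 1/(n_resample + 1). Under independence the expected TS is
n_pairs · E|r| with E|r| = 2/((n−2)·B(½,(n−2)/2)) ≈ √(2/(π(n−1))) for n
samples — the suite checks this against Monte-Carlo.

## The synthetic-cohort generator

The generator emulates the structure of a two-cohort germline study so
each downstream stage sees realistic inputs with known truth:

- **Population structure**: Balding–Nichols. Each common variant draws an
  ancestral frequency p ~ U(0.05, 0.5); each subpopulation with divergence
  F (Fst) draws its frequency from Beta(p(1−F)/F, (1−p)(1−F)/F); genotypes
  are Binomial(2, freq). Cohort composition is allocated by largest
  remainder, so configured proportions are exact.
- **Carriers**: per gene, logit P(carrier) = logit(baseline) + β·I(case) +
  γ_pop, with β = planted Log2OR·ln 2 — the burden test's estimand equals
  the planted value by construction. Carrier status is simulated at gene
  level and each carrier receives one qualifying truncating variant;
  collapsing makes this equivalent to variant-by-variant simulation while
  keeping fixtures small. An optional cancer-type restriction confines the
  effect to one tumor type.
- **LOH** (case samples only, since copy-number states exist only for
  tumors): logit P(minor CN = 0) = logit(baseline LOH) + d·I(carrier);
  non-LOH samples draw minor CN from {1, 2} (0.8/0.2).
- **Features/expression**: per-cluster Gaussians (TAU clipped to [0,1],
  LOEUF floored at 10⁻³); per-group multivariate normal expression with
  equicorrelation ρ (valid down to −1/(p−1); ρ = 1 gives the rank-one,
  perfectly correlated panel used to exercise the TS upper bound).

One integer seed drives everything; each stage derives an independent
stream via `SeedSequence([seed, stage_index])`, so identical config + seed
reproduces outputs exactly, and the LOH/feature simulators are
reproducible without re-running the cohort simulator.

What the generator does **not** emulate: linkage disequilibrium between
variants, per-nucleotide mutation processes, sex chromosomes, relatedness,
sequencing artifacts that differ between cohorts, or segment-level CNA
structure. Passing tests therefore demonstrate the statistical machinery
(calibration, confounding control, effect recovery, FDR control) under the
stated generative assumptions — not robustness to the platform and
annotation heterogeneity of real merged cohorts.

## Problem sizes used in tests and the acceptance script

Null calibration uses 2,000 genes at 600+600 samples (5% baseline carrier
frequency) through the full PC-adjusted pipeline; confounding control uses
1,000 genes at 600+600 with an 80:20/20:80 two-population split, Fst 0.1
and a two-fold population difference in carrier frequency; effect recovery
uses 200 replicates per planted Log2OR ∈ {1, 2, 3} at 1.5% baseline and
2,000+2,000 samples; FDR control uses 100 replicates of 200 genes (10%
alternatives at Log2OR 3) at 1,000+1,000; two-hit recovery uses 2,000
tumors with 5% baseline LOH and planted coupling Log2OR 3. These sizes
give stable Monte-Carlo estimates while keeping a full run of the suite
and the acceptance script in the low minutes on one CPU.

## Known limitations

- The unadjusted no-covariate test on collapsed 2×2 tables has discrete
  p-values; uniformity diagnostics (KS) are meaningful only for the
  covariate-adjusted model.
- Wald p-values are the default (a likelihood-ratio option is not
  provided); at very low carrier counts Wald inference is conservative,
  which the eligibility thresholds mitigate by design.
- `single_cancer_run` subsets pre-computed PC scores rather than
  recomputing PCA within the restricted cohort; after restriction to one
  population the residual structure is second-order.
- The gene-set rank-sum reference group (zero / complement / another set)
  is a user choice; the three options can disagree for small sets, and no
  single default is asserted as canonical.
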