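# Methods

`cfrnaflow` implements the downstream, count-level half of a plasma cfRNA
analysis: everything from tabular upstream-tool output to classifier
evaluation. This note documents the statistical procedures, the synthetic
cohort model used to exercise them, the numerical conventions, and the
design choices that were genuinely open.

## Quality gate

A sample passes only if all eight thresholds hold with *strict*
inequalities: raw reads > 10,000,000; clean reads > 5,000,000; deduplicated
aligned reads > 500,000; spike-in fraction < 0.5; rRNA fraction < 0.5;
mRNA+lncRNA ratio > 0.2; unclassified-read ratio < 0.3; intron-spanning
read pairs > 100,000. Boundary cases are vanishingly unlikely on real
libraries, so the literal strict reading costs nothing and keeps the gate
unambiguous. The rules are independent thresholds: all are always
evaluated, every violation is reported, and the decision is per sample with
no cohort-level renormalization after removal. A missing metric raises a
validation error naming the field — a sample can never pass by omission.

## Microbial consensus and decontamination

Reads unassigned to the human genome are classified by two independent
taxonomy pipelines (k-mer profile and alignment). A genus is *detected* by
a pipeline when at least `min_reads` (default 3) reads appear in at least
`min_samples` (default 3) samples; only genera detected by **both**
pipelines enter downstream analysis. The detection rule is applied to each
pipeline independently (not to a per-sample union/intersection of the two,
which the source protocol leaves unstated); raising either threshold can
only shrink the consensus set.

Contamination filtering is presence-based set subtraction, applied in a
fixed order used solely so each genus's ledger entry names one rule:

1. `control_sample` — bacterial/archaeal genera with ≥ 3 reads in any
   negative control; viral genera with ≥ 3 reads in an *E. coli* control
   (other controls are not informative for viral carry-over);
2. `lab_list` — published common laboratory contaminants;
3. `skin_list` — genera abundant on human skin. The list is a precomputed
   input (species with CPM > 10 in an external skin dataset); recomputing
   it would require that dataset, so list construction is an input
   contract, not a pipeline step;
4. `virus_host` — viral genera whose species infect nonhuman eukaryotic
   hosts.

Because every rule is a subtraction, the kept set is order-independent.
Genus-name matching is exact and case-sensitive after whitespace trimming;
no taxonomy-synonym resolution is attempted. The ledger covers every input
genus exactly once (`not_consensus` entries included), so kept ∪ removed
partitions the input.

## Normalization

**TMM factors.** For sample *k* against reference *r*, over genes positive
in both libraries: M_g = log2((y_gk/N_k)/(y_gr/N_r)),
A_g = ½·log2((y_gk/N_k)(y_gr/N_r)). Genes in the top/bottom 30% of M or
top/bottom 5% of A are trimmed (average ranks; `floor(n·trim)+1 …
n−floor(n·trim)` retained). The factor is 2 raised to the weighted mean of
the retained M with delta-method inverse-variance weights
1/((N_k−y_gk)/(N_k·y_gk) + (N_r−y_gr)/(N_r·y_gr)); factors are rescaled to
geometric mean 1. The reference is the sample whose 75th-percentile CPM is
closest to the mean of those percentiles — the originating method's
convention. Agreement with an independently coded step-by-step computation
is tested to 1e-10 on random matrices; exact edge-case parity with every
corner of the R implementation is not claimed. A sample sharing no
positively expressed gene with the reference is an error; a trim window
that empties falls back to factor 1.

**Expression scale.** Downstream stages consume log2(CPM+1), with CPM on
effective (factor-scaled) library sizes. The +1 pseudocount keeps
zero-inflated genus profiles finite and stable.

**Empirical control genes.** Per feature, a one-way fixed-effects ANOVA of
log2(CPM+1) across sample groups; the ⌈25%⌉ of features with the largest
p-values are taken as controls ("stably expressed among groups"). The
source protocol screened with a count-model quasi-likelihood ANOVA; that
GLM machinery is out of scope here and the F-test on log-CPM substitutes
with the same screening intent. Degenerate features get deterministic
p-values — zero variance everywhere → p = 1 (selected first), zero
within-group variance with between-group differences → p = 0 — and ties
break by stable feature order, so selection is permutation-equivariant up
to that rule.

**RUVg.** Control-gene log-expression is centered per gene across samples;
the rank-k SVD of the centered control submatrix gives sample-side factors
W (scaled by singular values; signs fixed so each factor's
largest-magnitude loading is positive). Every feature is regressed on
[1, W] by least squares and the W component subtracted. k is unspecified
in the source protocol; the default k = 1 matches the single dominant
center/batch factor in the simulation design and is configurable. Human
and genus matrices are normalized separately by default (each feature
space selects its own controls), also configurable. With k ≥ the rank of
the control matrix the call errors; zero-variance controls return the
input unchanged.

## Differential abundance

Feature-wise Mann–Whitney rank-sum tests between two groups on the CPM
scale, Benjamini–Hochberg FDR (the de facto default of the cited
toolchain; the source says only "FDR"), and effect sizes
log2((mean_A+1)/(mean_B+1)) on group mean CPM. Significance is the
conjunction |log2FC| > 1 and q < 0.05. The count-model quasi-likelihood
fits of the original toolchain are deliberately not re-implemented; this
rank-based module is the repository's differential method, reported at the
same thresholds. An optional exclusion list (e.g. known sex-associated
genes) drops features before testing. For one-vs-rest cancer comparisons
the comparator pools the remaining cancers without healthy donors by
default (configurable).

The rank-sum p-value is exact (full enumeration of the U null
distribution) when both arms have ≤ 10 observations and the pooled values
are tie-free; otherwise the normal approximation with tie and continuity
corrections is used. The screening loops in classification use the
vectorized asymptotic path throughout.

## Bootstrap classification protocol

Per replicate: a training multiset of cohort size is drawn with
replacement; the never-drawn samples form the holdout (expected fraction
(1−1/n)^n ≈ 0.368). Draws are repeated (bounded at 100) until both train
and holdout contain every class — holdout metrics are undefined otherwise,
and a size-1 class is reported as an error naming the class.

**Feature selection** runs only on the training multiset: in each of 10
rounds a stratified 75% subsample is drawn (stratification avoids empty
classes in small cohorts; the source protocol does not say), every feature
is scored by rank-sum between classes — every unordered class pair in the
multiclass task — and the 50 smallest-p features per comparison are
recorded (ties by stable feature order); the union over pairs and rounds
is kept. The two-class multiclass case reduces exactly to the binary
selector.

**Balanced random forest.** Each of 100 CART trees (Gini, √p candidate
features per split, tuned maximum depth) trains on a bootstrap drawing,
for every class, minority-class-size instances with replacement, so every
tree sees equal class counts. Prediction averages per-tree class
probabilities. Maximum depth is tuned by stratified cross-validation
(default fivefold, reduced with a warning when the smallest class is
smaller) over {3, 5, 7, 10, unbounded}, scoring holdout-fold AUROC (two
classes) or macro top-1 recall (≥ 3); ties prefer the smallest depth.
Tuning is re-run per replicate (the literal reading of the protocol),
configurable. Importance is mean impurity decrease, ranked descending
within each replicate (rank 1 = most important).

**Reports.** Binary: per-replicate holdout AUROC plus an out-of-bag ROC
built from each sample's *median* held-out positive-class probability
(samples never held out are excluded with a warning). Multiclass:
holdout confusion counts row-normalized per replicate then averaged;
top-1 recall is the diagonal; top-2 recall counts holdout samples whose
true class is among the two highest predicted probabilities (probability
ties broken by fixed class order); average recall is the unweighted mean
of per-class top-1 recalls. Recurrent-feature tables count how often a
feature's importance rank falls within a cutoff (reference protocol:
top-50 rank in ≥ 40 of 100 replicates) and attach fold changes vs a
comparator group. Feature-set comparisons (e.g. human+microbe vs
human-only per-replicate recall) use a one-tailed Mann–Whitney test.

**Seeding.** Replicate r uses `numpy.random.default_rng([seed, r])`, and
the generator derives per-stage streams the same way, so every stage and
every replicate is independently reproducible and results do not depend on
execution order. Reports are bit-identical across reruns at the JSON
level; numeric output is written with 10 significant digits.

**Normalization order.** TMM + RUVg run once on the full cohort *before*
bootstrapping, mirroring the source protocol's stated order. The holdout
estimates therefore share normalization information across the
train/holdout boundary; this is a property of the design being
re-implemented, not an implementation artifact (see Limitations).

## Synthetic cohort model

The generator emulates the tabular inputs with the statistical structure
the analysis assumes, not the sequencing process:

- **Human counts:** negative binomial with variance μ + φμ², φ = 0.2 by
  default; per-gene baseline proportions log-normal (σ = 1); library sizes
  log-normal (median 2×10⁶, σ = 0.25 on the log scale) — plasma cfRNA
  libraries are shallow after deduplication. Each non-healthy group gets
  `n_de_per_group` planted features at |log2FC| = `de_log2fc` (random
  sign), disjoint across groups; a batch factor (default 2 levels,
  per-gene log2 effects of SD `batch_log2_sd` = 0.5) multiplies **all**
  features, so RUVg has signal to remove; control-eligible genes are the
  unplanted ones.
- **Genus tables:** one latent negative-binomial draw (microbial totals
  ~2% of the human library) classified "twice": the k-mer table reports
  the latent counts and the alignment table is per-count binomial thinning
  with retention 1 − `pipeline_noise` (default 0.3) — mimicking one read
  set processed by two classifiers, so the tables are coupled rather than
  independent. Kingdom composition is fixed (65/25/10
  bacteria/virus/archaea, shuffled). Planted contaminants are injected at
  high abundance into every cohort sample (so they clear consensus) and
  with ≥ 3 reads into at least one control profile; each carries an
  expected ledger rule in the truth record, with the lab/skin/virus-host
  rules exercised through viral contaminants placed in a non-E.-coli
  control plus the matching list.
- **QC metrics:** passing samples draw comfortably inside every threshold;
  a designed fraction violates exactly one rule each (rules assigned
  round-robin), recorded in the truth.
- **Reference conditions:** the defaults — 2 groups × 60 samples, 2000
  genes, 100 planted at |log2FC| = 2, dispersion 0.2 — define the binary
  study conditions. The five-cancer experiments use 6 groups × 40 with a
  deliberately moderate human signal (30 features per cancer at
  |log2FC| = 0.9, dispersion 0.35) so recall has headroom below 1, plus a
  strongly informative genus space (10 genera per cancer at |log2FC| = 2),
  echoing the observation that microbial profiles carry tumor-site
  information of their own. Effect sizes and variance structure of the
  real cohort are not published at this granularity; these values are the
  package's own choice of a realistic regime, fixed once.

What the generator does **not** model: fragment-length and coverage
profiles, per-gene GC or length bias, taxonomic misclassification
structure (beyond thinning), overdispersion heterogeneity across genes,
and correlated gene modules. Passing tests therefore demonstrate that the
pipeline recovers the structure it assumes when that structure is present
— not that real cfRNA cohorts satisfy those assumptions.

## Desk-scale protocol sizes

The reference protocol uses 100 bootstrap replicates and the five-point
depth grid. The packaged experiments (`cfrnaflow.experiments`, used by the
test suite and `scripts/acceptance.py`) run 20 replicates with a reduced
depth grid ({5, unbounded}, threefold CV) for the binary tasks and 20
replicates at unbounded depth for the multiclass tasks (6–8 replicates per
seed in the multi-seed gain comparison); with strongly class-specific
features depth tuning adds little. These are problem-size choices of the
packaged experiments; the protocol logic is identical at any setting.

## Known limitations

- **Empirical-control circularity.** Selecting control genes by ANOVA
  against the same labels later classified is a whole-cohort,
  label-dependent step. On signal-free data, re-running control selection
  against permuted labels inflated null holdout AUROC to ≈ 0.9 (vs ≈ 0.5
  with label-independent controls): removing a factor estimated from the
  "least label-associated" genes enriches the remainder in chance label
  association that generalizes within the finite cohort. The packaged
  null therefore permutes labels *after* normalization, which isolates
  the resampling protocol; a permutation test of the full design
  (normalization included) would need the control screen inside the
  resampling loop.
- **Cohort-level normalization** before bootstrapping (the design's stated
  order) means holdout performance is not a fully external estimate.
- The rank-based differential module and F-test control screen substitute
  for the original count-model GLM fits; thresholds and intent match,
  per-feature p-values will not.
- Genus-level, presence-based decontamination cannot separate a genuine
  signal genus that also appears in controls; abundance-model
  decontamination is out of scope.
- The balanced forest treats class imbalance by per-tree balanced
  bootstraps only; probability calibration is not attempted.
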