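# Methods

This note documents the models and procedures implemented in `tauaging`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data experiments do and do not establish.

## Study design being modelled

The pipeline targets a longitudinal single-cell study of a tauopathy model:
flies expressing human tau pan-neuronally versus driver-only controls,
brains dissociated and profiled at 1, 10 and 20 days (one library per
genotype × age in the discovery design), plus a replicated design with
three libraries per genotype at day 10.  Cells carry cluster labels
produced upstream (normalization-integration-clustering is out of scope
here; cluster membership is an input to every stage).

## Quality control and normalization

Cells are retained when the number of detected genes lies in [200, 3000]
and the mitochondrial count fraction is at most 20%.  The bounds are
boundary-inclusive: the removal rule is a strict inequality on either side
(fewer than 200, more than 3000, more than 20%).  Mitochondrial genes are
recognized by the fly `mt:` identifier prefix by default, with an explicit
override list.

Expression is depth-normalized per cell — counts divided by the cell's UMI
total, multiplied by 10,000, ln(1+x)-transformed — and, for cross-dataset
profile comparisons, z-scored per gene with the population (ddof = 0)
standard deviation; zero-variance genes become zero rows with a warning.

The cellular detection rate (CDR) is the fraction of the gene universe
detected in a cell.  The expected droplet-multiplet proportion is the
linear loading model Y = 5.272·10⁻⁴ + 7.589·10⁻⁶·x (x = recovered cells),
clamped to [0, 1]; it is a reporting device, not a filter.

## Hurdle differential expression

Each gene's ln-normalized expression y within one cluster is modelled in
two parts:

- detection: logit P(y > 0) = Xβ (logistic regression, Newton-Raphson,
  batched across genes sharing a design);
- level: y | y > 0 = Xγ + ε, fit by unpenalized least squares on the
  detected cells with a maximum-likelihood variance.

A group effect is tested by a likelihood-ratio statistic summed over both
parts, with degrees of freedom summed over the parts that carry them (a
gene detected in all or in none of the cells contributes no detection df;
a gene with too few detected cells for a full-rank level fit contributes
no level df).  CDR is always a covariate; the genotype contrast adds age
in days as a numeric covariate.  No empirical-Bayes variance shrinkage or
logistic priors are applied: at the cell counts this pipeline targets
(hundreds per group) the unshrunk fits are already calibrated, as the
type-I-error experiments verify.

Numerical choices:

- Covariates are standardized inside the fit (log-likelihood-invariant);
  without this, the near-constant CDR column makes the Newton system
  ill-conditioned and the test badly anticonservative.
- CDR is additionally centred within each contrast group.  Large planted
  (or real) expression programs shift the global detection rate of one
  group; an outcome-contaminated covariate that correlates with the group
  indicator makes truly unchanged genes load on the group coefficient.
  Group-centring restores CDR to its technical role.  This is a deliberate
  divergence from the common convention of using raw CDR.
- Perfect separation in the detection part is handled by a small ridge
  (10⁻⁶) on the logistic coefficients; such fits are flagged.
- In the batched per-cluster test the level part's contribution is
  calibrated through the exact F distribution on the detected subset
  (converted to a chi-square-equivalent before summing with the detection
  part) — the finite-sample-correct form of the Gaussian likelihood
  ratio.  The single-gene `hurdle_lrt` keeps the plain summed
  log-likelihood formula.
- Genes are tested only when detected in ≥ 10% of cells of at least one
  group — identical to the reporting filter, so the significant set is
  unchanged and degenerate fits are avoided.

Significance within a cluster: BH-adjusted p < 0.05, |avg_log2FC| > 0.1
(difference of group means of ln values divided by ln 2, numerator first),
detection ≥ 10%.  BH is applied within each (cluster, contrast) family.
Aging contrasts compare consecutive ages within controls (1 vs 10, 10 vs
20), with the later age as numerator.  The tau/aging overlap statistic is
|union(tau) ∩ union(aging)| / |union(tau)| over per-cluster significant
sets, with per-cluster fractions where both contrasts name the cluster.

## Differential cell abundance

Per-library cell counts per cluster are treated as count data.  Library
size factors are DESeq-style median-of-ratios: rows with any zero are
excluded from the geometric-mean reference, with an optional +0.5
pseudo-count mode.  (Note one algebraic subtlety: scaling one library's
column by c scales the factor *ratio* by exactly c, while every factor
also absorbs a common c^(1/J) geometric-mean term; cross-library
normalized ratios are what the procedure preserves.)

Each cluster's counts are fit with an NB-GLM (log link, log size factors
as offsets) under `count ~ age + genotype` (discovery; age numeric) or
`count ~ genotype` (replication).  Dispersion is estimated per cluster by
adjusted profile likelihood (Cox–Reid correction), floored at 10⁻⁸, with a
method-of-moments fallback; no cross-cluster empirical-Bayes moderation is
attempted — with a dozen to a few hundred clusters and six libraries the
trend machinery is underdetermined, and the permutation-calibration
experiment covers the consequences.  The genotype coefficient is
Wald-tested and converted to log2 (coefficient / ln 2); BH across
clusters.

Optional shrinkage replaces mixture-prior adaptive shrinkage with a
single-normal empirical-Bayes rule: prior variance = max(0, var(log2FC) −
mean(lfcSE²)); shrunk = log2FC · priorVar/(priorVar + lfcSE²).  It is off
by default and used for reporting scale only.

Because cluster proportions are closed (sum to one), a true decline in one
population inflates everything else.  The anchored analysis subtracts each
reference-class (glial/hemocyte) cluster's log2FC from every cluster's
value; the min and max of these differences bound the true change under
the assumption the anchors are biologically unchanged.  The ranges are
bounds, not probabilistic intervals; anchors always contain zero through
self-subtraction.

## Consensus annotation

A reference atlas holds cluster centroids (mean lognorm expression),
ranked top-k marker lists, and a similarity feature list.  Features are
the 500 genes with higher-than-expected dropout: residuals of a linear fit
of logit(dropout) on log mean expression, largest positive first (genes
with zero dropout are never selected ahead of positive residuals).
Markers are one-vs-rest hurdle-DE genes with positive log2FC > 0.1 at BH
p < 0.05, ranked by descending log2FC; the "rest" group is capped at 2,000
cells by a deterministic evenly-spaced subsample.

Cell-level mapping: cosine, Pearson and Spearman similarity to every
centroid; each measure votes for its argmax (abstaining on exact ties); a
cell maps to R when ≥ 2 measures vote R and the best voting score exceeds
0.7.  Cluster-level: the majority mapped reference, accepted when it
covers > 50% of mapped cells.  Marker intersection maps a query cluster at
≥ 13/20 shared top markers (whole-brain convention; 7/20 for an optic-lobe
style reference), ties broken by Jaccard over full marker lists, then
lexicographically with a tie flag.  Channels (similarity vote, marker
map, optional external classifier table, optional literature checklist)
consolidate to a consensus label when two or more agree; one channel gives
a single-source label; disjoint agreeing pairs flag a conflict.  An
optic-lobe priority switch resolves flagged conflicts toward the
classifier label.

## Gene-set activity

Mean activity is the per-cell mean of member-gene lognorm expression
(missing members dropped and logged; empty sets yield missing columns).
The AUC variant ranks genes within each cell by expression (descending,
ties by ascending gene index — a deterministic convention), counts
cumulative set-member recovery over the top 5% of ranks (k_max =
floor(0.05·G)) and normalizes the curve area.  Two normalizations are
implemented because the reference tool's constant is version-dependent:
mode A divides by k_max·min(|S|, k_max); mode B (default) divides by the
best achievable curve's area, so a set occupying the top ranks scores
exactly 1.

Cluster activity log2FC is the log2 ratio of genotype mean activities
(defined for non-negative activities; z-scored inputs are rejected toward
a difference mode).  Differential activity per (cluster, set) is a
Gaussian LRT of `activity ~ genotype + age` against `~ age` (1 df), BH
across sets within cluster.

## Elastic-net vulnerability ranking

The design restricts to clusters with significant decline (BH p < 0.05 and
log2FC < 0); predictors are cluster-level mean activities over cells
pooled across genotypes and ages, standardized (population sd), constant
columns dropped.  The solver minimizes (1/2n)Σr² + λ(α‖β‖₁ + (1−α)/2‖β‖₂²)
by cyclic coordinate descent with soft-thresholding, intercept
unpenalized, convergence at max coefficient change < 10⁻⁷.  Tuning is
repeated k-fold cross-validation (default 3 folds; the full 100 repeats of
the original design is configurable, smaller defaults keep desk-scale
runtimes) over α ∈ [0, 1] and a log-spaced λ path from λ_max down to
λ_max·10⁻⁴, warm-started down the path; the winner minimizes mean RMSE
with ties toward larger λ, then larger α, and is refit on all rows.  With
about eight rows against a hundred-plus predictors the model is a ranking
device, not an inferential fit; predictors are reported by coefficient
magnitude, and the headline association is the Pearson correlation between
a set's cluster activity and abundance log2FC over the declining clusters.

## Cross-species correspondence

Ortholog candidates below score 5 are dropped; among survivors the cascade
is highest score → highest weighted score → best-forward-and-reverse flag
→ lexicographically smallest target (flagged).  Multiple sources may keep
the same target (pair counting); a strict-injection mode exists for
set-overlap work.  Cluster × gene matrices of mean z-scores are correlated
(Pearson) over the resolved ortholog features for every cluster pair;
display order comes from average-linkage hierarchical clustering on 1 − r.
Gene-set overlap uses the upper-tail hypergeometric distribution, exact
against enumeration on small universes.

## The synthetic-data generator

The generator is the package's study-conditions definition, not a fixture.
Defaults: 12 clusters (8 neuronal including two Kenyon-cell-like, 3 glial,
1 hemocyte-like; glia + hemocyte are the anchor class), 1,000 genes (10
mitochondrial), 150 cells per cluster per library (~1,800 per library,
scaled down from ~8,000 in a real run), six discovery libraries, 183
regulons of 15 genes, 150 aging-responsive and 100 tau-responsive genes
with 93% of the tau set drawn from the aging set, planted |log2FC| = 1,
NB size parameters lognormal around 10, lognormal cell depths (σ = 0.35).

Structure: gamma base means per gene; disjoint 25-gene marker blocks
(boost ×8) give clusters their identity; lognormal cluster-gene jitter
(σ = 0.15) decorrelates the rest.  Aging effects are a geometric
progression — each age step (1→10, 10→20) multiplies an aging gene by
2^(±effect) — in every cluster; tau effects apply only in the "polarized"
affected-cluster subset.  The first regulon is immune-like (Rel/NFκB
style): member means scale with a planted per-cluster activity a ∈ [0, 1]
(factor 1 + a) and are further multiplied ×2 in tau cells of affected
clusters.  Planted abundance change is −β·a + noise for non-anchor
clusters (β = 1.5 by default), exactly 0 for anchors, realized by scaling
multinomial cluster weights by 2^log2FC in tau libraries; an explicit
per-cluster override exists for parameter-recovery experiments.

Two generator choices matter for interpreting results:

- Planted DE genes (and regulon members) are drawn from expressed genes
  (baseline mean ≥ 0.25), so recovery measures the method rather than
  assay depth.
- Planted directions are assigned mass-balanced (greedy over baseline
  means), so planted effects leave total mRNA content unchanged.  Without
  this, per-cell normalization converts the planted mass shift into a
  genuine relative change of every unchanged gene (compositional closure),
  and no calibrated test can keep the false-discovery rate near nominal
  against a planted-indicator truth.  Closure effects still arise where
  they are unavoidable (e.g. the one-sided regulon activation, and the
  accumulated aging progression at day 20); they are real phenomena of
  relative-abundance data, and the anchored abundance analysis exists for
  exactly this reason.

What the generator does **not** emulate: batch effects, ambient RNA,
doublets, spatial structure, zero-inflation beyond NB zeros, library-level
random effects, or realistic gene-gene correlation beyond the planted
sets.  Passing the validation suite therefore shows the pipeline's
statistics are calibrated and its estimators recover truth under a clean
NB world at desk scale; it does not certify performance on real droplet
data.

## Validation experiment sizes

The validation module fixes desk-scale problem sizes chosen so the full
suite runs in minutes: null calibration at 300 cells × 2,000 genes with
equal cell depths (the clean NB null — under lognormal depth variation the
linear-CDR detection model is mildly misspecified, and the per-cell depth
couples genes so dataset-level rejection rates over-disperse); DE
recovery at 300 cells per group with 200 planted genes in 2,000; overlap
recovery over 10 seeds with six clusters (one tau-affected, regulon
activation off so the planted 93% partition is the only tau signal) at 120
cells per cluster per library; abundance recovery on the replicated design
with planted log2FC ∈ {−1, 0, +0.5} on three clusters (modest planted mass
keeps the closure renormalization small against the ±0.3 tolerance);
annotation and cross-species round trips at 60 cells per cluster per
library; determinism on a 25-cell-per-cluster full pipeline run.

## Known limitations

- The hurdle level part assumes approximate normality of detected ln
  values; at very low detection counts the χ² reference is approximate
  (mildly inflated far tails), which matters mostly to union-type
  statistics that accumulate false positives across many families.
- The abundance Wald test ignores dispersion-estimation uncertainty at
  n = 6 libraries; the permutation-null experiment bounds the practical
  consequence, and estimates on genuinely NB-overdispersed (rather than
  multinomial) counts would be anticonservative.
- Anchored ranges are deterministic bounds given the anchor assumption;
  they carry no coverage probability.
- The elastic net at n ≈ 8 is a ranking device; coefficients have no
  standard errors and rank stability across seeds is the meaningful
  output.
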