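# Methods

This note documents the statistical models the package implements, the
choices made where the design was genuinely open, what the synthetic
generator does and does not emulate, and the known limitations.

## Differential expression

Counts are transformed to log2-CPM as `log2((count + 0.5) / (libsize + 1) *
1e6)`. Before modelling, genes pass a two-part inclusion filter: the
median-of-ratios mean normalized count must be ≥ 20 (inclusive), and the
gene must be detected (count > 0, equivalently CPM > 0 at any library size)
in at least `ceil(case_fraction × n)` samples, where the case fraction is
taken from the analysed subset. The ceiling is our rounding choice; the rule
itself has no stated rounding. Size factors are computed on the subset being
analysed, and the reference set for the geometric means excludes any gene
with a zero (a pseudo-reference over nonzero entries is available behind
`allow_pseudo_reference`).

Each gene is fit by weighted least squares against a design of intercept +
case status + covariates (age group, sex, library batch, site, RIN, GC,
ancestry PCs 1–2). Categorical covariates are treatment-coded with the
lexicographically smallest level as reference so design matrices are
reproducible; age enters as a binary adult/pediatric indicator, matching the
stratified analyses the covariate set is built for.

Precision weights follow the mean–variance trend approach: per-gene
sqrt-residual-sd is regressed on mean log2 count by LOWESS (span 0.5), the
trend is evaluated at each observation's fitted log-count, and the weight is
the inverse fourth power. With fewer than 50 genes the trend is unreliable
and unit weights are used with a warning.

The moderated t shrinks per-gene residual variances toward a common prior:
`s̃² = (d0·s0² + d·s²)/(d0 + d)` with `(d0, s0²)` estimated by
method-of-moments on log residual variances (digamma/trigamma moment
matching, trigamma inverted by Newton iteration). `t = b/(se_unscaled · s̃)`
is referred to a t distribution on `d0 + d` df (normal when `d0 = ∞`).
Setting `d0 = 0` reproduces ordinary least squares exactly; this identity is
tested against a direct normal-equation solve. Multiple testing uses
Benjamini–Hochberg step-up, tested against exhaustive enumeration.

### Latent factors

Unmeasured confounding (batch residue, cell-composition drift) is adjusted
by residual PCA: principal components of the expression (or methylation)
matrix after regressing out the known design. `k = "auto"` selects
components by parallel analysis — observed eigenvalues are kept while they
exceed the 95th percentile of eigenvalues from 20 within-row permutations of
the residual matrix. This is a deliberate, deterministic substitute for
surrogate-variable and Bayesian factor methods: it preserves their role
(data-driven confounder adjustment) with a reproducible algorithm. The
pipeline defaults fix k = 60 for the eQTM models and k = 12 for the DMC
scan, honouring the configuration the analysis design calls for at its
intended panel sizes.

**Caveat (measured):** forcing a fixed k onto a much smaller feature panel
overfits noise components. On null panels of 100 CpGs, k = 12 produced a
family-wise error of 3/20 against a Bonferroni bound of ~2.9/20; with
`k = "auto"` (which returns ~0 factors under the null) control is exact.
Use `"auto"` when the tested feature set is small.

## Co-expression modules

Genes at q < 0.15 in the all-subjects differential expression feed the
network — a deliberately liberal net for a systems-level analysis. The
signed adjacency is `((1 + r)/2)^β` with Pearson r; β is the smallest
integer in 1..20 whose scale-free topology fit R² (regression of log10 p(k)
on log10 k over 10 connectivity bins, sign-flipped if the slope is positive)
reaches 0.9, falling back to the argmax with a warning. Signed topological
overlap is `TOM_ij = (L_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)` with
`L_ij = Σ_{u≠i,j} a_iu·a_uj`; it is verified against a literal triple-loop
evaluation.

Module detection is average-linkage clustering on 1 − TOM with a **static
cut at the largest gap among the upper half of merge heights**, then pruning
of clusters below 15 genes to label 0 (unassigned). A fixed-height cut is
unusable here because TOM dissimilarities saturate toward 1 as β grows; the
largest near-root gap separates within-module merges from between-module
merges at any β, and recovers planted blocks at ARI ≈ 1. This is a
simplified, deterministic stand-in for dynamic hybrid tree cutting, which is
not fully specified anywhere we could implement from; the package's
correctness claim is planted-structure recovery, not label-for-label
agreement with any particular study's module list.

Module expression is the mean of member genes' log2-CPM residualized against
sex, batch, RIN and GC (intercept retained so values stay on the expression
scale). Module differential expression reuses the moderated fit across
module means with the full covariate set (one-module inputs fall back to
OLS, flagged). Hubs maximise intramodular connectivity `Σ_j a_ij`, with ties
to the lexicographically smaller gene id; an external interaction table
(edges with score > 0.15) may replace the adjacency as the connectivity
source. The module graph links pairs with Pearson r strictly > 0.5,
positive correlations only.

## Cumulative multi-module risk

The three most significant modules by q-value (configurable) are
residualized against age group, sex, site, RIN, GC, batch and ancestry PCs,
then dichotomized at the median over **all** samples (the alternative,
within-controls medians, is not used): an up-in-cases module scores 1
strictly above its median, a down-in-cases module strictly below; ties at
the median score 0 (the conservative reading of "upper median"). Directions
come from the sign of the module-DE log2FC, and a direction of exactly 0 is
an error requiring explicit input. The per-sample count of risk-side
modules (0..K) enters a logistic model as a numeric term, so
`OR_k = exp(k·β̂)` holds exactly; confidence intervals are Wald
(`exp(kβ̂ ± 1.96·k·SE)`). Departures from additivity are tested by a
likelihood-ratio test against the factor-coded model, with
`df = (#observed levels − 1) − 1` (2 when all four levels of a three-module
count are observed); with fewer than three observed levels the models
coincide and the test is skipped.

## Methylation cascade

Stage order is enforced: genes significant at q < 0.05 → candidate CpGs →
eQTM → DMC → peak selection → conditional adjustment; each stage consumes
only survivors of the previous.

Candidate pairs are CpGs within 5 kb of the gene's TSS (inclusive, either
direction; TSS = start for '+', end − 1 for '−', all coordinates 0-based
half-open) or inside an enhancer linked to the gene by promoter-capture
HiC. A pair satisfying both is labelled `tss5kb`. Selecting pairs before
testing, rather than scanning a wide window and filtering afterwards, gives
the same test set at less compute.

eQTM models regress log2-CPM on methylation beta plus the full DE covariate
set and latent factors, on the samples shared by both assays (intersection
rule); significance is uncorrected p < 0.05 by design — the stage is a
screen, and family-wise control arrives at the DMC stage. The DMC scan is a
moderated fit of beta on case status (age group, sex, site, batch, PCs,
latent factors) over the unique eQTM CpGs, with the Bonferroni threshold
0.05/M computed from the tested count M, never hard-coded; variance
moderation shares information across the tested CpG set only. Methylation
effects are reported on the beta scale throughout; expression stays on
log2-CPM.

Genes with several surviving CpGs get a peak CpG from one joint model of
expression on all of them plus covariates (smallest joint-model p;
near-collinear CpGs at |r| > 0.999 drop to the first by genomic position,
with a warning). The conditional model then refits the gene's disease
effect with and without the peak CpG's beta column and reports
`attenuation = 1 − log2FC_adj / log2FC_unadj`. The verdict
`consistent-with-mediation` requires attenuation ≥ 0.5 **and** loss of
significance (p_adj > 0.05); both thresholds are package-defined
(configurable) formalizations of a qualitative judgement, and a CpG nearly
collinear with case status (point-biserial |r| > 0.99) is flagged rather
than trusted. Case-only follow-up regressions of methylation on CASI
severity and on ICS use report standardized coefficients.

## Replication

Internal results join an external meta-analysis summary table on gene id;
external duplicates resolve to the row with the most contributing studies k
(ties: larger |effect|, then id). n_total is the matched-gene count.
Enrichment is the upper tail P(X ≥ overlap) of
Hypergeometric(n_total, n_external_sig, n_internal_sig), verified against
combinatorial enumeration. External significance uses q when the table has
it, else p with a flag. Direction concordance is the equal-sign fraction in
the double-significant overlap; nominal replication counts external
p < 0.05 with matching sign outside that overlap.

## Synthetic cohorts

The generator emulates the data structure the analysis assumes, with known
ground truth:

- **Design**: 253 cases / 283 controls over seven sites with unequal case
  fractions and sample shares (defaults mirror the motivating study's
  recruitment); batch round-robin within site so batch is partially
  confounded with site; site case fractions differ so covariate adjustment
  is non-trivially exercised.
- **Covariates** (declared defaults — no source states these
  distributions): sex male ~ Bernoulli(0.38); adult ~ Bernoulli(0.70);
  RIN ~ N(7.5, 0.8²) clipped to [1, 10]; GC ~ N(0.47, 0.02²); ancestry
  PCs ~ N(0, 0.05²); case CASI = 1 + Poisson(3); IgE and phadiatop
  log-normal with higher case means.
- **Counts**: NB(mean, φ) with Var = μ + φμ², φ = 0.1 by default; mean =
  libsize × baseline × 2^(case·log2FC + Σ loading·module latent +
  slope·(beta − ½) + batch and GC nuisance + biological noise). Library
  sizes are log-normal (median 8M). Per-gene biological noise (log2 sd
  0.35) keeps disease status a minor share of gene variance, as in real
  cohorts; without it, planted modules collapse into up/down-in-case
  superclusters.
- **Modules**: per-module latent factors are multivariate normal with a
  configurable inter-module correlation and a case/control mean shift;
  member genes load on their latent.
- **Methylation**: M-values Gaussian (within-group sd 0.45, i.e. beta-scale
  sd ≈ 0.10, typical of arrays), reported as beta = logistic(M). For
  complete-mediation triplets, case status shifts the CpG (group beta means
  straddle 0.5 by ± shift/2) and the gene's expression is generated from
  the beta value with **no direct case term**; none-type triplets have an
  expression-driving CpG with no case shift plus a direct disease effect on
  the gene. The mediator's M-values come from a child RNG stream keyed only
  on the design seed, so `generate_counts` and `generate_methylation` agree
  without sharing state.
- **Determinism**: identical seed + design give bit-identical outputs; the
  pipeline fans one global seed out to per-stage child seeds by stable
  hashing of stage names, so toggling one stage never shifts another's
  randomness.

What the generator does **not** emulate: raw reads or array idats, genotype
structure beyond two covariate PCs, count outliers and GC/length biases
beyond a linear GC term, methylation probe artefacts, relatedness, or
missing data (the models reject missing covariates by contract).
Consequently, passing tests demonstrate correct statistical machinery and
recoverability under the assumed data-generating process — not robustness
to the full messiness of real cohorts.

## Problem sizes and numerical choices

Desk-scale defaults are 2,000 genes × 536 samples and 5,000 CpGs
(configurable upward); calibration checks use 20 seeds of 500-sample,
2,000-gene null cohorts, recovery checks use n = 500 for fold-changes,
n = 300 for methylation effects, and n = 50,000 for the risk-model slope.
The full pipeline on the default bundle runs in seconds on one CPU.
Tolerances: planted log2FC = 1 recovered within ±0.1; module ARI > 0.8 at
within-module r ≥ 0.6; risk log-odds within ±0.05 at n = 50,000 with the
OR_k = OR_1^k identity exact; beta-scale DMC effect −0.3 within ±0.05;
≥ 80% of complete-mediation triplets (and ≤ 10% of none-type) receive the
mediation verdict across 20 seeds. Degenerate inputs fail loudly by
contract: rank-deficient designs name the offending columns, constant
contrasts and empty CpG sets raise, complete separation in the logistic fit
is detected via exploding standard errors, and a TOM larger than the block
limit (8,000) refuses rather than approximating block-wise.

## Known limitations

- The moderated-t machinery assumes approximately normal log-CPM residuals;
  very low counts are handled only through the precision weights.
- The static gap cut cannot split nested modules the way dynamic hybrid
  cutting can; deeply nested correlation structure will merge.
- The mediation verdict is conditional adjustment, not causal mediation
  analysis: no indirect-effect confidence intervals, and measured-mediator
  noise biases attenuation toward zero.
- Fixed latent-factor counts are anticonservative on small feature panels
  (measured above); prefer `"auto"` there.
- The replication stage consumes an external summary table as given; it
  performs no meta-analysis and no identifier mapping beyond exact id join.
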