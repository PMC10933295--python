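# Methods

This note documents the models and procedures implemented in `osteomix`,
the assumptions behind them, the parameters that matter, and the design
choices made where the underlying methodology left the details open.

## Data model and transforms

All omics matrices are features × samples. Each modality carries value
semantics that are validated on load and respected by every simulation
step: methylation beta values in [0,1], metabolite abundances positive,
microbiota relative abundances summing to one per sample. Statistical
work happens on a per-modality *analysis scale*: logit(beta) for
methylation (M-value-like), log for metabolites, and a centered log-ratio
(CLR) with a half-minimum pseudocount for microbiota. These transforms
make the linear-model and correlation machinery downstream defensible on
otherwise bounded or compositional data. Genotypes are additive dosages
{0,1,2} with missing calls as NaN; VCF positions are 1-based and BED
intervals 0-based half-open, with the conversion (`pos − 1 ∈ [start,
end)`) unit-tested at the boundaries.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
so every downstream stage can be tested without any external data:

* **Cohort shape.** Default 91 normal / 158 osteopenia / 117
  osteoporosis (366 samples), fully configurable. Two subtypes exist
  only inside the osteoporosis group, split by `subtype_fraction`
  (default 0.5).
* **Molecular signal.** Each modality has `n_signature` features
  (default 12 of 300) carrying (a) a disease gradient of
  `group_effect_size` z-units (default 1.0) from normal through
  osteopenia to osteoporosis and (b) a subtype mean shift of
  `effect_size` z-units (default 1.5) between the two osteoporosis
  subtypes, with random sign per feature, on the modality's analysis
  scale. The subtype signal is *split across modalities*: each modality
  carries its own disjoint signature set that is small relative to the
  feature space, so a single modality under-determines the subtypes and
  fusing all three recovers them better than any one alone. The
  signature counts were fixed once, at a size where that regime holds,
  before the recovery tests were written.
* **Noise models.** Methylation is simulated on the logit scale and
  mapped back by the inverse logit; metabolites are log-normal;
  microbiota are logistic-normal followed by closure onto the simplex.
* **Correlation rewiring.** Planted cross-modal feature pairs receive a
  positive Spearman correlation in subtype 1 and a negative one in
  subtype 2 (defaults ±0.6) via a Gaussian copula per stratum; the
  latent Pearson correlation is set to `2·sin(π·ρ_s/6)` so the sample
  Spearman lands near the target, and per-stratum margins are
  preserved.
* **Genotypes.** Variants are drawn at Hardy–Weinberg proportions with
  MAFs uniform on `maf_range` (default 0.05–0.5) and 1% missingness.
  Planted QTLs add `qtl_beta` (default 0.8) standard deviations of the
  target feature per alt allele on the analysis scale.
* **Phenotypes and fracture.** Clinical columns (age, sex, BMI, smoking
  and drinking history, bone turnover markers, hip and lumbar BMD
  indices, prior fracture, follow-up BMD change) follow the disease
  gradient; subtype 1 gets lower total-hip/femoral-neck BMD and higher
  lumbar L1–L4 BMD than subtype 2 (`bmd_subtype_contrast`, default
  0.06 g/cm² per site). The binary fracture outcome comes from a
  logistic model on subtype-2 membership (+1.6 log-odds), femoral-neck
  BMD (−1.0 per z) and prior fracture (+0.9), intercept −2.6. The
  subtype-2 coefficient is deliberately larger than the BMD pathway so
  that subtype 2 fractures more *despite* its higher hip BMD — the
  qualitative pattern the fracture-risk stages are designed to detect.
* **Determinism.** All randomness flows from one seed through named
  sub-streams (one per modality and component), so enlarging one
  modality never perturbs another, and identical configs give
  bit-identical cohorts.

What the generator does **not** emulate: array chemistry, sequencing
reads, batch effects, imputation uncertainty, longitudinal trajectories,
or realistic linkage disequilibrium. Tests passing on these cohorts show
the pipeline recovers the structure it assumes; they do not certify
performance on real cohorts, where effect sizes, correlation structure
and confounding are unknown.

## DLSF: deep latent space fusion

Each modality gets a two-layer tanh autoencoder (default width
min(64, p), latent dimension 16) with a self-expression layer on the
bottleneck: sample latents satisfy Z ≈ C·Z with diag(C) = 0. The joint
objective per modality is

    λ_rec‖X − Dec(Z)‖² + λ_se‖Z − C Z‖² + λ_reg‖C‖²,

trained full-batch with a hand-written Adam (lr 1e-3), 150 epochs of
reconstruction-only pretraining followed by 150 joint epochs during
which C is refreshed every 25 epochs by its exact solution given Z.

Two numerical choices matter and are worth spelling out:

* **Nonnegative coefficients.** After per-feature standardization, two
  mean-shifted clusters sit at ±μ and span the *same* linear subspace,
  so the classical unconstrained ridge self-expression expresses any
  sample equally well with either cluster (with flipped signs) and
  |C| + |C|ᵀ carries no block structure at all. Constraining C ≥ 0
  (row-wise NNLS on the ridge-augmented system) removes the antipodal
  escape route: a sample cannot be a nonnegative combination of the
  opposite cluster. The unconstrained closed form (C = −A/diag(A) with
  A = (ZZᵀ + λI)⁻¹, the KKT elimination of the diagonal constraint)
  remains available as a fast fallback and as the oracle that the
  training path is tested against.
* **Energy-scaled penalty.** The effective ridge λ is
  `λ_reg/λ_se · mean‖z_i‖²`. Because the latent dimension is far below
  the sample count, a weak penalty lets the underdetermined system
  spread coefficients across all samples; scaling λ with the latent
  energy drives C toward a thresholded inner-product kernel whose block
  structure tracks the clusters, and keeps behaviour stable as the
  latent scale changes during training.

Per-modality affinities `normalize(|C| + |C|ᵀ)` (unit maximum) are
averaged into one fused affinity, clustered by normalized-cut spectral
clustering (symmetric-normalized Laplacian, bottom-k eigenvectors,
row-normalized, k-means with 50 seeded restarts). Labels are
canonicalized to first-appearance order so repeated runs are
byte-identical. The cluster count is chosen over k ∈ {2,3,4} by
maximizing the number of clinical phenotypes associated at P < 0.05,
subject to a cluster-balance floor (normalized entropy ≥ 0.7), ties
going to the smaller k. By default clustering is applied to the
osteoporosis stratum only (`--population op`); clustering the whole
cohort is supported.

## Landscape and QC statistics

* **SNP QC:** call rate ≥ 0.95, MAF ≥ 0.05 (computed on non-missing
  calls), and an exact Hardy–Weinberg test at p ≥ 1e-5. The HWE test is
  the exact conditional test with the "probability ≤ observed" two-sided
  rule, computed in log space and verified against a full-enumeration
  oracle; the chi-square approximation is avoided because it misbehaves
  at low minor-allele counts.
* **Differential screens:** two-sided Wilcoxon rank-sum per feature,
  exact null distribution when both groups have ≤ 25 tie-free samples,
  tie-corrected normal approximation otherwise. Screens use raw
  P < 0.05; Benjamini–Hochberg q-values are reported alongside but do
  not drive the screens.
* **RV index** between modalities uses the standard trace formula on
  column-centered matrices; **co-expression** networks are Spearman
  graphs per sample group with a configurable |ρ| edge threshold.

## DAM and M3S

Stratum-specific Spearman association matrices are compared with the
Fisher z statistic, `z = (atanh ρ₁ − atanh ρ₂)/√(1/(n₁−3) + 1/(n₂−3))`,
two-sided normal p. Sign flips are reported when the correlations have
opposite signs and both magnitudes reach 0.3 (the magnitude bar is a
reporting choice; the rewiring p-value does not depend on it).
Discovery lists use BH-FDR 0.05; raw P < 0.05 views are retained.

The stemness-like weighting is a one-class ridge regression of a
constant one-target on the reference stratum's analysis-scale profiles:
w ∝ (XXᵀ + λI)⁻¹X·1 with a scale-free λ (1e-3 of the mean feature
energy), normalized to unit length; per-sample scores are Spearman
correlations with w, hence invariant to monotone rescaling of a sample's
values. M3S selection intersects the top-q features by |w| with the
Wilcoxon-significant features per modality, ordered by weight, falling
back to weights alone (with a warning) if the intersection is empty.
The reference stratum defaults to each osteoporosis subtype; it is a
parameter because the methodology leaves it open.

## xQTL

Per (variant, feature): OLS of the analysis-scale feature on dosage plus
covariates, Wald p for the dosage term, hits at the fixed threshold
P < 1e-5 with no further correction. Covariates default to age + sex +
top-8 genotype principal components (PCA on the QC-filtered,
mean-imputed, standardized dosage matrix). Missing dosages drop samples
pairwise per variant; stratum-monomorphic variants are skipped. The
global screen chi-square-tests the genotype-count × group table, pooling
to carrier/non-carrier when any expected cell is below 5. snpGene
annotation maps variants into gene intervals with a configurable flank
(default 10 kb, since "neighboring" distance is not pinned down), class
precedence exonic > intronic > intergenic.

## Risk models and fracture assessment

Three nested logistic tiers: Baseline I (age, BMI, drinking, smoking),
Baseline II (+ β-CTX, OST, PINP), and the full model (+ M3S features,
reduced by greedy mRMR with the mutual-information-difference criterion
on 4-bin equal-frequency discretized features, training split only,
lexicographic tie-breaks). Fits are maximum likelihood with a tiny L2
ridge (ε = 1e-6) for stability on standardized inputs; coefficients and
Wald standard errors are reported on the original scale. Evaluation is a
seed-fixed stratified 70/30 split with Mann–Whitney AUC (ties ½), DeLong
confidence intervals, ROC points, and decision-curve net benefit
`TP/n − (FP/n)·pt/(1−pt)` with treat-all/treat-none references. Gender
enters optionally (`--with-gender`).

Fracture assessment scores every candidate feature by AUC against the
fracture outcome in the ALL population and the osteoporosis-only (OP)
population, with per-feature orientation so reported AUCs are ≥ 0.5 and
a candidate bar at AUC > 0.6. Adjusted AUCs residualize the feature on
three covariate schemes — (1) age + gender, (2) + prior fracture,
(3) + femoral-neck BMD — by least squares within the population before
re-scoring; residualization-then-AUC is a deterministic choice made
here because the adjustment mechanism is not otherwise specified. The
composite screen exhaustively enumerates panels of one to four
candidates; the panel score is the sum of member values after
orientation, z-scored within the population by default (`--raw-sum`
reproduces the literal sum of raw values). The published five-feature
osteoporosis panel, sixteen-feature subtype panel and four-CpG fracture
panel ship as data files (`osteomix.load_panel`) for scoring user
tables.

## Problem sizes in the test and acceptance runs

The test suite and `scripts/acceptance.py` run the full chain on cohorts
of the default shape (366 samples, 300 features per modality, 200
variants), with 10–20 simulation seeds for recovery and ordering
statistics, 2000-test null batches for calibration, and 10 resamples at
80% for stability. These sizes were chosen so a complete run finishes in
a few minutes on one CPU while keeping Monte-Carlo error well inside the
asserted margins.

## Known limitations

* The acceptance-style ordering of held-out AUCs across the three risk
  tiers is a statement about medians; in any single 70/30 split the
  m3s-over-Baseline-II margin is of the same order as split noise under
  the default generator, so individual seeds can invert that pair.
* Self-expression is O(n²)–O(n³) per update; the implementation targets
  cohort-scale n (hundreds), not biobank scale.
* The generator's group gradient makes signature features informative
  for both disease group and subtype; studies wanting orthogonal
  signals should configure separate effect sizes.
* Spectral clustering assumes the fused affinity graph is connected;
  more components than clusters is an error by design rather than a
  silent per-component fallback.
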