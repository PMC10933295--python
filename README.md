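# osteomix

Multi-omics subtyping and fracture-risk analysis for osteoporosis
cohorts.

Osteoporosis is diagnosed from a single number — the BMD T-score — yet
patients with the same T-score differ widely in fracture risk and in
their response to intervention such as calcium supplementation. This
package implements an integrative analysis pipeline for cohorts profiled
on three molecular modalities (DNA methylation, serum metabolites, gut
microbiota) plus genotypes and clinical phenotypes, aimed at
computational biologists and biostatisticians working on disease
subtyping: it discovers molecular subtypes of the osteoporosis group,
characterizes them, and turns the resulting signatures into risk models
and fracture-risk indices.

## What it computes

**Deep latent space fusion (DLSF) subtyping.** Per modality *m*, a
two-layer autoencoder with a self-expression layer on its bottleneck
minimizes

&nbsp;&nbsp;λ_rec‖X_m − Dec_m(Z_m)‖² + λ_se‖Z_m − C_m Z_m‖² + λ_reg‖C_m‖²,&nbsp;&nbsp; diag(C_m) = 0, C_m ≥ 0,

so each sample's latent vector is a (nonnegative) combination of the
other samples' latents. The coefficient matrices are fused into one
sample affinity S = mean_m normalize(|C_m| + |C_m|ᵀ), and normalized-cut
spectral clustering of S yields candidate subtypes; the cluster count
k ∈ {2,3,4} is selected by clinical-phenotype association count under a
cluster-balance floor.

**Downstream characterization and clinical models.**

* molecular-landscape statistics: per-feature Wilcoxon screens
  (P < 0.05), cross-modality RV indices, Spearman co-expression graphs;
* SNP QC (call rate ≥ 95%, MAF ≥ 5%, exact Hardy–Weinberg test at
  p ≥ 1e-5) and xQTL scans — OLS of each molecular feature on allele
  dosage with age, sex and top-8 genotype PCs, hits at P < 1e-5 — with
  interval-based snpGene annotation;
* differential association matrices (DAM): stratum-specific Spearman
  matrices compared by Fisher z, flagging correlation sign flips between
  subtypes;
* stemness-like one-class weighting and M3S (multi-modal molecular
  signature) selection;
* nested logistic risk models (Baseline I: conventional risk factors;
  Baseline II: + bone turnover markers; full model: + M3S via mRMR),
  evaluated by a stratified 70/30 split with Mann–Whitney AUC, DeLong
  CIs and decision curves;
* fracture-risk assessment: per-feature oriented AUC in the whole
  cohort (ALL) versus the osteoporosis group only (OP), three
  covariate-adjusted AUC schemes, and exhaustive screening of composite
  sum-indices over panels of up to four features.

A synthetic cohort generator (`osteomix.simulate`) produces full
cohorts — three omics modalities, genotypes, phenotypes, fracture
outcomes — with planted subtypes, rewired correlations and QTL effects,
so the entire pipeline is testable end to end without any data download.
See `docs/methods.md` for models, assumptions and parameter defaults.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from osteomix.simulate import SimulationConfig, generate_cohort
from osteomix.dlsf import DlsfConfig, subtype_cohort
from osteomix.evaluate import balance_index
from osteomix.fracture import feature_auc_ranking

cohort = generate_cohort(SimulationConfig(seed=1))   # 91/158/117 samples
labels = cohort.truth["labels"]
op_mask = (labels["group"] == "osteoporosis").to_numpy()

assign, report, _ = subtype_cohort(
    cohort.omics, cohort.phenotypes, DlsfConfig(seed=1),
    population_mask=op_mask, sample_ids=cohort.omics[0].sample_ids,
    phenotype_columns=["th_bmd", "fn_bmd", "l1l4_bmd", "beta_ctx",
                       "ost", "pinp", "followup_bmd_delta"],
)
truth = labels.loc[op_mask, "subtype"].to_numpy()
print(f"selected k = {assign.k}")
print(f"cluster balance = {balance_index(assign.labels):.3f}")
print(f"ARI vs planted subtypes = {adjusted_rand_score(truth, assign.labels):.3f}")

pheno = cohort.phenotypes.table
ranking = feature_auc_ranking(
    pheno[["fn_bmd", "th_bmd", "l1l4_bmd"]],
    pheno["fracture"].to_numpy(), population="ALL",
)
print(ranking[["feature_id", "orientation", "auc"]].to_string(index=False))
```

Output:

```
selected k = 2
cluster balance = 1.000
ARI vs planted subtypes = 1.000
feature_id  orientation      auc
    fn_bmd           -1 0.722982
  l1l4_bmd           -1 0.672062
    th_bmd           -1 0.634763
```

The model selects two perfectly balanced clusters inside the 117-sample
osteoporosis group and recovers the planted subtypes exactly (adjusted
Rand index 1.0 on this seed). The fracture ranking shows the BMD indices
predicting fracture in the whole cohort with orientation −1 — *lower*
BMD means higher risk — with femoral-neck BMD the strongest, exactly the
clinical pattern the generator encodes.

A command-line interface mirrors the library stage by stage:

```sh
osteomix simulate --config config.yaml --out cohort/
osteomix qc        --data cohort/ --out qc/
osteomix subtype   --data cohort/ --seed 1 --out subtype/
osteomix dam       --data cohort/ --labels subtype/subtype_labels.csv --out dam/
osteomix m3s       --data cohort/ --labels subtype/subtype_labels.csv --out m3s/
osteomix xqtl      --data cohort/ --labels subtype/subtype_labels.csv \
                   --bed genes.bed --out xqtl/
osteomix risk      --data cohort/ --signatures m3s/m3s_signatures.tsv --out risk/
osteomix fracture  --data cohort/ --signatures m3s/m3s_signatures.tsv --out fracture/
```

Every stage logs its resolved configuration and writes deterministic
outputs: re-running with the same config and seed reproduces each file
byte for byte.

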