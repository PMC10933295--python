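"""Synthetic multi-omics osteoporosis cohort generator.

Emulates the statistical structure the analysis pipeline assumes: a
three-group cohort (normal / osteopenia / osteoporosis, default sizes
91/158/117), two planted subtypes inside the osteoporosis group whose
mean-shift signal is split across the three molecular modalities,
subtype-specific correlation rewiring between cross-modal feature pairs,
planted additive genotype effects on molecular features, and a binary
fracture outcome driven by subtype, femoral-neck BMD and prior fracture
through a logistic model.

Value semantics per modality are respected by construction: methylation is
simulated on the logit scale and mapped back through the inverse logit so
beta values stay in [0,1]; metabolites are log-normal; microbiota are
logistic-normal followed by closure onto the simplex.

All randomness flows from a single seed through named sub-streams (one per
modality / component), so enlarging one modality does not perturb the
draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .transforms import clr, inv_logit, logit
from .types import (
    GenotypeMatrix,
    MODALITIES,
    OmicsMatrix,
    PhenotypeTable,
)

_STREAMS = {
    "labels": 0,
    "methylation": 1,
    "metabolite": 2,
    "microbiota": 3,
    "genotypes": 4,
    "phenotypes": 5,
    "fracture": 6,
    "rewiring": 7,
    "qtl": 8,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], int(seed)])


@dataclass
class FractureModel:
    """Logistic model for the binary fracture outcome (log-odds scale)."""

    intercept: float = -2.6
    beta_subtype2: float = 1.6     # subtype-2 raises risk beyond its BMD
    beta_fn_bmd: float = -1.0      # per z-unit of FN BMD; low BMD -> risk
    beta_prior_fracture: float = 0.9


@dataclass
class SimulationConfig:
    """Cohort shape, planted effect sizes and noise structure.

    The default group sizes mirror the study cohort (91 normal, 158
    osteopenia, 117 osteoporosis).  ``effect_size`` is the standardized
    mean shift of each signature feature between the two osteoporosis
    subtypes on its modality's analysis scale.  The subtype signal is
    split across modalities in that each modality carries its own
    disjoint set of ``n_signature`` signature features; the per-modality
    signature counts are deliberately small relative to the feature
    space, so a single modality under-determines the subtypes and their
    fusion recovers them better than any one modality alone.
    """

    n_normal: int = 91
    n_osteopenia: int = 158
    n_osteoporosis: int = 117
    subtype_fraction: float = 0.5
    n_features: dict = field(
        default_factory=lambda: {
            "methylation": 300, "metabolite": 300, "microbiota": 300,
        }
    )
    n_signature: dict = field(
        default_factory=lambda: {
            "methylation": 12, "metabolite": 12, "microbiota": 12,
        }
    )
    effect_size: float = 1.5        # total subtype shift, z-units
    group_effect_size: float = 1.0  # normal -> osteoporosis gradient, z-units
    rewiring_pairs: int = 8
    rho_pos: float = 0.6
    rho_neg: float = -0.6
    n_variants: int = 200
    n_qtl_effects: int = 5
    qtl_beta: float = 0.8           # per alt allele, z-units of the feature
    maf_range: tuple = (0.05, 0.5)
    genotype_missing_rate: float = 0.01
    bmd_subtype_contrast: float = 0.06  # per-site BMD shift between subtypes
    fracture_model: FractureModel = field(default_factory=FractureModel)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_normal", "n_osteopenia", "n_osteoporosis"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.subtype_fraction < 1.0:
            raise ValueError("subtype_fraction must be in (0,1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 0.5) and not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if isinstance(self.fracture_model, dict):
            self.fracture_model = FractureModel(**self.fracture_model)

    @property
    def n_samples(self) -> int:
        return self.n_normal + self.n_osteopenia + self.n_osteoporosis


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth used to plant it."""

    omics: list            # of OmicsMatrix, one per modality
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    truth: dict            # labels (DataFrame), signatures, rewiring, qtl

    @property
    def sample_ids(self) -> list[str]:
        return list(self.truth["labels"].index)


# ---------------------------------------------------------------------------
# helper: latent (analysis-scale) construction per modality


def _subtype_indicator(labels: pd.DataFrame) -> np.ndarray:
    """+-0.5 contrast inside osteoporosis, 0 elsewhere."""

    z = np.zeros(len(labels))
    z[(labels["subtype"] == 1).to_numpy()] = 0.5
    z[(labels["subtype"] == 2).to_numpy()] = -0.5
    return z


def _group_gradient(labels: pd.DataFrame) -> np.ndarray:
    grade = {"normal": 0.0, "osteopenia": 0.5, "osteoporosis": 1.0}
    return labels["group"].map(grade).to_numpy()


def _latent_modality(config: SimulationConfig, modality: str,
                     labels: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Features x samples Gaussian latent with planted signatures."""

    rng = _rng(config.seed, modality)
    p = config.n_features[modality]
    n = config.n_samples
    z = rng.standard_normal((p, n))
    n_sig = min(config.n_signature[modality], p)
    sig_idx = np.arange(n_sig)  # first features carry signal; IDs say so
    subtype = _subtype_indicator(labels)
    gradient = _group_gradient(labels)
    signs = rng.choice([-1.0, 1.0], size=n_sig)
    for i, s in zip(sig_idx, signs):
        z[i] += s * (config.effect_size * subtype + config.group_effect_size * gradient)
    prefix = {"methylation": "cg", "metabolite": "met", "microbiota": "taxon"}[modality]
    ids = [
        f"{prefix}_sig{i:04d}" if i < n_sig else f"{prefix}_{i:04d}"
        for i in range(p)
    ]
    return z, ids


def _observe(modality: str, latent: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """Map an analysis-scale latent to observed modality values."""

    p = latent.shape[0]
    if modality == "methylation":
        baseline = rng.normal(0.0, 1.2, size=(p, 1))
        return inv_logit(baseline + latent)
    if modality == "metabolite":
        baseline = rng.normal(3.0, 0.8, size=(p, 1))
        return np.exp(baseline + 0.5 * latent)
    if modality == "microbiota":
        baseline = rng.normal(0.0, 1.5, size=(p, 1))
        logits = baseline + latent
        expv = np.exp(logits - logits.max(axis=0, keepdims=True))
        return expv / expv.sum(axis=0, keepdims=True)
    raise ValueError(modality)


# ---------------------------------------------------------------------------
# operations


def generate_genotypes(n_samples: int, n_variants: int,
                       maf_range=(0.05, 0.5), seed: int = 0,
                       missing_rate: float = 0.0,
                       sample_ids=None) -> GenotypeMatrix:
    """Draw variants at Hardy-Weinberg proportions with uniform MAFs."""

    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = _rng(seed, "genotypes")
    mafs = rng.uniform(lo, hi, size=n_variants)
    dosages = rng.binomial(2, mafs[None, :], size=(n_samples, n_variants)).astype(float)
    if missing_rate > 0:
        miss = rng.random((n_samples, n_variants)) < missing_rate
        dosages[miss] = np.nan
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    variants = pd.DataFrame(
        {
            "id": [f"rs{i:06d}" for i in range(n_variants)],
            "chrom": ["1"] * n_variants,
            "pos": np.arange(1, n_variants + 1) * 1000,
            "ref": ["A"] * n_variants,
            "alt": ["G"] * n_variants,
        }
    )
    return GenotypeMatrix(list(sample_ids), variants, dosages)


def plant_rewiring(omics: list, subtype_labels: pd.Series, pairs: list,
                   rho_pos: float, rho_neg: float, seed: int = 0) -> list:
    """Give feature pairs opposite correlations in the two subtypes.

    ``pairs`` is a list of ((modality_a, feature_a), (modality_b,
    feature_b)).  Within each subtype stratum the two features' values are
    redrawn from a Gaussian copula whose Pearson correlation is chosen so
    the *Spearman* correlation comes out near the requested rho
    (``rho_pearson = 2 sin(pi * rho_s / 6)``); margins (per-stratum mean
    and spread on the analysis scale) are preserved.
    """

    for rho in (rho_pos, rho_neg):
        if abs(rho) >= 1:
            raise ValueError("|rho| must be < 1")
    if not pairs:
        return omics
    rng = _rng(seed, "rewiring")
    by_mod = {m.modality: m for m in omics}
    analysis = {
        mod: _analysis_scale_matrix(by_mod[mod]) for mod in by_mod
    }
    subtype_labels = np.asarray(subtype_labels)
    for (mod_a, fa), (mod_b, fb) in pairs:
        ia = by_mod[mod_a].feature_ids.index(fa)
        ib = by_mod[mod_b].feature_ids.index(fb)
        for subtype, rho_s in ((1, rho_pos), (2, rho_neg)):
            mask = subtype_labels == subtype
            n = int(mask.sum())
            if n < 2:
                continue
            rho_p = 2.0 * np.sin(np.pi * rho_s / 6.0)
            cov = np.array([[1.0, rho_p], [rho_p, 1.0]])
            draw = rng.multivariate_normal([0.0, 0.0], cov, size=n).T
            for row, (mod, idx) in zip(draw, ((mod_a, ia), (mod_b, ib))):
                old = analysis[mod][idx, mask]
                analysis[mod][idx, mask] = old.mean() + old.std() * row
    out = []
    for m in omics:
        obs = _from_analysis_scale(m.modality, analysis[m.modality], by_mod[m.modality])
        out.append(OmicsMatrix(m.modality, list(m.feature_ids),
                               list(m.sample_ids), obs, m.value_semantics))
    return out


def _analysis_scale_matrix(m: OmicsMatrix) -> np.ndarray:
    if m.value_semantics == "beta01":
        return logit(m.values)
    if m.value_semantics == "positive_abundance":
        return np.log(m.values + 1e-12)
    # relative abundance: plain log; closure is re-applied on the way back
    return np.log(m.values + 1e-12)


def _from_analysis_scale(modality: str, analysis: np.ndarray,
                         template: OmicsMatrix) -> np.ndarray:
    if template.value_semantics == "beta01":
        return inv_logit(analysis)
    if template.value_semantics == "positive_abundance":
        return np.exp(analysis)
    expv = np.exp(analysis - analysis.max(axis=0, keepdims=True))
    return expv / expv.sum(axis=0, keepdims=True)


def generate_fracture_outcomes(phenotypes: PhenotypeTable, truth: pd.DataFrame,
                               fracture_model: FractureModel,
                               seed: int = 0) -> PhenotypeTable:
    """Draw the binary fracture outcome from the logistic model."""

    for col in ("fn_bmd", "prior_fracture"):
        if col not in phenotypes.table.columns:
            raise ValueError(f"phenotypes lack required column {col!r}")
    rng = _rng(seed, "fracture")
    fn = phenotypes["fn_bmd"].to_numpy(dtype=float)
    fn_z = (fn - fn.mean()) / fn.std()
    pf = phenotypes["prior_fracture"].to_numpy(dtype=float)
    sub2 = (truth["subtype"] == 2).to_numpy().astype(float)
    logits = (
        fracture_model.intercept
        + fracture_model.beta_subtype2 * sub2
        + fracture_model.beta_fn_bmd * fn_z
        + fracture_model.beta_prior_fracture * pf
    )
    prob = inv_logit(logits)
    outcome = (rng.random(len(prob)) < prob).astype(int)
    table = phenotypes.table.copy()
    table["fracture"] = outcome
    return PhenotypeTable(table)


def _generate_phenotypes(config: SimulationConfig,
                         labels: pd.DataFrame) -> PhenotypeTable:
    rng = _rng(config.seed, "phenotypes")
    n = config.n_samples
    grad = _group_gradient(labels)           # 0 / 0.5 / 1
    sub = _subtype_indicator(labels)         # +0.5 subtype1, -0.5 subtype2

    age = rng.normal(62 + 8 * grad, 7)
    sex = (rng.random(n) < 0.78).astype(int)   # 1 = female
    bmi = rng.normal(24.5 - 1.0 * grad, 3.0)
    smoking = (rng.random(n) < (0.15 + 0.12 * grad)).astype(int)
    drinking = (rng.random(n) < (0.20 + 0.10 * grad)).astype(int)

    # bone turnover markers: elevated remodeling in disease
    beta_ctx = rng.lognormal(np.log(0.35) + 0.45 * grad, 0.35)
    ost = rng.lognormal(np.log(14.0) + 0.35 * grad, 0.30)
    pinp = rng.lognormal(np.log(42.0) + 0.40 * grad, 0.35)
    alp = rng.lognormal(np.log(70.0) + 0.15 * grad + 0.10 * sub, 0.20)

    # BMD indices; subtype 1 lower at hip sites, higher at lumbar spine
    bc = config.bmd_subtype_contrast
    th_bmd = rng.normal(0.95 - 0.20 * grad - bc * sub * 2, 0.07)
    fn_bmd = rng.normal(0.90 - 0.22 * grad - bc * sub * 2, 0.07)
    l1l4_bmd = rng.normal(0.98 - 0.25 * grad + bc * sub * 2, 0.08)
    l1l4_bmdz = (l1l4_bmd - l1l4_bmd.mean()) / l1l4_bmd.std()

    prior_fracture = (rng.random(n) < (0.08 + 0.15 * grad)).astype(int)
    # 2-year follow-up: subtype-1 BMD improves under intervention
    followup = rng.normal(0.02 * (sub > 0) * 2 - 0.005 * grad, 0.012)

    table = pd.DataFrame(
        {
            "group": labels["group"].to_numpy(),
            "age": age, "sex": sex, "bmi": bmi,
            "smoking": smoking, "drinking": drinking,
            "beta_ctx": beta_ctx, "ost": ost, "pinp": pinp, "alp": alp,
            "th_bmd": th_bmd, "fn_bmd": fn_bmd,
            "l1l4_bmd": l1l4_bmd, "l1l4_bmdz": l1l4_bmdz,
            "prior_fracture": prior_fracture,
            "followup_bmd_delta": followup,
        },
        index=labels.index,
    )
    return PhenotypeTable(table)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort with ground truth."""

    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    group = (
        ["normal"] * config.n_normal
        + ["osteopenia"] * config.n_osteopenia
        + ["osteoporosis"] * config.n_osteoporosis
    )
    n_sub1 = int(round(config.subtype_fraction * config.n_osteoporosis))
    n_sub1 = min(max(n_sub1, 1), config.n_osteoporosis - 1)
    subtype = [0] * (config.n_normal + config.n_osteopenia)
    subtype += [1] * n_sub1 + [2] * (config.n_osteoporosis - n_sub1)
    labels = pd.DataFrame({"group": group, "subtype": subtype}, index=sample_ids)

    omics = []
    signatures = []
    for modality in MODALITIES:
        latent, ids = _latent_modality(config, modality, labels)
        obs = _observe(modality, latent, _rng(config.seed, modality))
        omics.append(
            OmicsMatrix(modality, ids, sample_ids, obs)
        )
        n_sig = min(config.n_signature[modality], config.n_features[modality])
        signatures += [(modality, ids[i]) for i in range(n_sig)]

    # subtype-specific rewiring between non-signature cross-modal pairs
    rew_rng = _rng(config.seed, "rewiring")
    pairs = []
    if config.rewiring_pairs > 0:
        mods = [m.modality for m in omics]
        for k in range(config.rewiring_pairs):
            mod_a, mod_b = mods[k % 3], mods[(k + 1) % 3]
            ma = next(m for m in omics if m.modality == mod_a)
            mb = next(m for m in omics if m.modality == mod_b)
            free_a = [f for f in ma.feature_ids if "_sig" not in f]
            free_b = [f for f in mb.feature_ids if "_sig" not in f]
            fa = free_a[int(rew_rng.integers(len(free_a)))]
            fb = free_b[int(rew_rng.integers(len(free_b)))]
            pairs.append(((mod_a, fa), (mod_b, fb)))
        omics = plant_rewiring(
            omics, labels["subtype"], pairs,
            config.rho_pos, config.rho_neg, seed=config.seed,
        )

    genotypes = generate_genotypes(
        n, config.n_variants, config.maf_range, seed=config.seed,
        missing_rate=config.genotype_missing_rate, sample_ids=sample_ids,
    )

    # planted additive genotype -> molecular feature effects
    qtl_rng = _rng(config.seed, "qtl")
    qtl_triples = []
    if config.n_qtl_effects > 0:
        variant_idx = qtl_rng.choice(
            config.n_variants, size=config.n_qtl_effects, replace=False
        )
        new_omics = {m.modality: _analysis_scale_matrix(m) for m in omics}
        for j, vi in enumerate(variant_idx):
            modality = MODALITIES[j % 3]
            m = next(o for o in omics if o.modality == modality)
            free = [f for f in m.feature_ids if "_sig" not in f]
            fid = free[int(qtl_rng.integers(len(free)))]
            fi = m.feature_ids.index(fid)
            dose = np.nan_to_num(genotypes.dosages[:, vi], nan=0.0)
            arr = new_omics[modality]
            arr[fi, :] = arr[fi, :] + config.qtl_beta * arr[fi, :].std() * dose
            qtl_triples.append(
                (genotypes.variants["id"].iloc[vi], modality, fid, config.qtl_beta)
            )
        omics = [
            OmicsMatrix(
                m.modality, list(m.feature_ids), list(m.sample_ids),
                _from_analysis_scale(m.modality, new_omics[m.modality], m),
                m.value_semantics,
            )
            for m in omics
        ]

    phenotypes = _generate_phenotypes(config, labels)
    phenotypes = generate_fracture_outcomes(
        phenotypes, labels, config.fracture_model, seed=config.seed
    )

    truth = {
        "labels": labels,
        "signatures": signatures,
        "rewiring": pairs,
        "qtl": qtl_triples,
    }
    return SyntheticCohort(omics, genotypes, phenotypes, truth)


# ---------------------------------------------------------------------------
# on-disk layout


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write the cohort in the package's standard layout.

    The truth CSVs are written alongside for benchmarking but are never
    read by analysis stages.
    """

    from pathlib import Path

    from . import io as omio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for m in cohort.omics:
        omio.write_omics(m, out / f"{m.modality}.tsv")
    omio.write_vcf(cohort.genotypes, out / "genotypes.vcf")
    omio.write_dosage_tsv(cohort.genotypes, out / "genotypes.dosage.tsv")
    omio.write_phenotypes(cohort.phenotypes, out / "phenotypes.csv")
    labels = cohort.truth["labels"].copy()
    labels.index.name = "sample_id"
    labels.to_csv(out / "truth_labels.csv")
    pd.DataFrame(
        cohort.truth["signatures"], columns=["modality", "feature_id"]
    ).to_csv(out / "truth_signatures.csv", index=False)
    pd.DataFrame(
        [
            (a[0], a[1], b[0], b[1])
            for a, b in cohort.truth["rewiring"]
        ],
        columns=["modality_a", "feature_a", "modality_b", "feature_b"],
    ).to_csv(out / "truth_rewiring.csv", index=False)
    pd.DataFrame(
        cohort.truth["qtl"],
        columns=["variant_id", "modality", "feature_id", "beta"],
    ).to_csv(out / "truth_qtl.csv", index=False)


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a SimulationConfig from a (possibly nested) config mapping."""

    d = dict(d.get("simulate", d))
    if "fracture_model" in d and isinstance(d["fracture_model"], dict):
        d["fracture_model"] = FractureModel(**d["fracture_model"])
    if "maf_range" in d:
        d["maf_range"] = tuple(d["maf_range"])
    return SimulationConfig(**d)
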