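"""Genotype -> molecular-phenotype association scans.

The xQTL scan regresses each molecular feature (on its modality's
analysis scale) on additive allele dosage plus covariates by ordinary
least squares, reporting the Wald p-value of the dosage coefficient; hits
are called at the fixed threshold P < 1e-5 with no further multiplicity
correction.  Covariates default to age + sex + the top genotype principal
components.  The global screen chi-square-tests the genotype-count by
sample-group contingency table per variant.  snpGene annotation maps
variants into (possibly flanked) gene intervals, converting the 1-based
variant position onto the 0-based half-open BED axis, with class
precedence exonic > intronic > intergenic.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .transforms import to_analysis_scale
from .types import GeneIntervalSet, GenotypeMatrix, OmicsMatrix


def genotype_pcs(genotypes: GenotypeMatrix, n_components: int = 8) -> np.ndarray:
    """Top principal components of the dosage matrix.

    Missing dosages are mean-imputed for the PCA only; columns are
    centered and scaled before decomposition.
    """

    d = genotypes.dosages.copy()
    col_mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(col_mean, inds[1])
    sd = d.std(axis=0)
    keep = sd > 0
    d = (d[:, keep] - d[:, keep].mean(axis=0)) / sd[keep]
    n_components = min(n_components, d.shape[0] - 1, d.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    return pca.fit_transform(d)


def _ols_scan_variant(dose, features, covariates):
    """OLS of every feature on [1, dose, covariates]; returns beta/se/p."""

    n = dose.size
    A = np.column_stack([np.ones(n), dose, covariates])
    k = A.shape[1]
    if n <= k:
        return None
    AtA = A.T @ A
    try:
        AtA_inv = np.linalg.inv(AtA)
    except np.linalg.LinAlgError:
        raise ValueError("collinear covariates in xQTL design") from None
    coef = AtA_inv @ (A.T @ features.T)          # k x n_features
    resid = features.T - A @ coef
    dof = n - k
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * AtA_inv[1, 1])
    beta = coef[1, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=dof)
    return beta, se, p


def qtl_scan(genotypes: GenotypeMatrix, molecular: OmicsMatrix,
             covariates=None, stratum_mask=None,
             p_threshold: float = 1e-5, stratum: str = "all",
             return_all: bool = False) -> pd.DataFrame:
    """Additive-model OLS scan of every (variant, feature) pair.

    Samples with a missing dosage are dropped pairwise per variant;
    variants monomorphic in the stratum are skipped.  Returns the hit
    table (p < threshold) or, with ``return_all``, every test.
    """

    if stratum_mask is None:
        stratum_mask = np.ones(genotypes.n_samples, dtype=bool)
    mask = np.asarray(stratum_mask, dtype=bool)
    if mask.sum() < 20:
        raise ValueError("stratum needs at least 20 samples")
    features = to_analysis_scale(molecular)[:, mask]  # features x n
    dosages = genotypes.dosages[mask, :]
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        covariates = covariates[mask, :] if covariates.shape[0] == genotypes.n_samples \
            else covariates
        if np.linalg.matrix_rank(
            np.column_stack([np.ones(covariates.shape[0]), covariates])
        ) < covariates.shape[1] + 1:
            raise ValueError("collinear covariates in xQTL design")
    rows = []
    fids = np.asarray(molecular.feature_ids)
    for j in range(genotypes.n_variants):
        dose = dosages[:, j]
        obs = ~np.isnan(dose)
        d = dose[obs]
        if d.size < 20 or np.ptp(d) == 0:
            continue
        cov = covariates[obs, :] if covariates is not None \
            else np.empty((d.size, 0))
        res = _ols_scan_variant(d, features[:, obs], cov)
        if res is None:
            continue
        beta, se, p = res
        sel = np.ones(p.size, dtype=bool) if return_all else (p < p_threshold)
        for fi in np.where(sel)[0]:
            rows.append((
                genotypes.variants["id"].iloc[j], fids[fi],
                molecular.modality, beta[fi], se[fi], p[fi], stratum,
            ))
    return pd.DataFrame(
        rows,
        columns=["variant_id", "feature_id", "modality", "beta", "se",
                 "p_value", "stratum"],
    )


def global_snp_test(genotypes: GenotypeMatrix, group_labels) -> pd.DataFrame:
    """Per-variant chi-square test of genotype counts across groups.

    The three genotype classes are pooled to two (carrier vs non-carrier)
    whenever any expected cell count falls below 5.
    """

    groups = np.asarray(group_labels)
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("need at least two sample groups")
    rows = []
    for j in range(genotypes.n_variants):
        dose = genotypes.dosages[:, j]
        obs = ~np.isnan(dose)
        d, g = dose[obs], groups[obs]
        table = pd.crosstab(d, g)
        if min(table.shape) < 2:
            rows.append((genotypes.variants["id"].iloc[j], np.nan, np.nan, False))
            continue
        arr = table.to_numpy(dtype=float)
        expected = np.outer(arr.sum(1), arr.sum(0)) / arr.sum()
        pooled = False
        if arr.shape[0] == 3 and (expected < 5).any():
            arr = np.vstack([arr[0], arr[1] + arr[2]])  # pool het + hom-alt
            pooled = True
            if (arr.sum(axis=1) == 0).any():
                rows.append((genotypes.variants["id"].iloc[j],
                             np.nan, np.nan, True))
                continue
        chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
        rows.append((genotypes.variants["id"].iloc[j], float(chi2),
                     float(p), pooled))
    return pd.DataFrame(rows, columns=["variant_id", "chi2", "p_value",
                                       "pooled"])


def annotate_snp_genes(genotypes: GenotypeMatrix, intervals: GeneIntervalSet,
                       flank_bp: int = 10_000,
                       variant_ids=None) -> pd.DataFrame:
    """Map variants to genes whose (flanked) interval contains them.

    A 1-based variant position ``pos`` lies inside a BED interval
    ``[start, end)`` iff ``start <= pos - 1 < end``; the flank widens the
    interval on both sides.  Variants inside an exon record are classed
    exonic, inside the gene but not an exon intronic, otherwise
    intergenic; a variant overlapping several genes keeps them all.
    """

    if flank_bp < 0:
        raise ValueError("flank_bp must be nonnegative")
    variants = genotypes.variants
    if variant_ids is not None:
        variants = variants[variants["id"].isin(set(variant_ids))]
    vcs = set(variants["chrom"].astype(str))
    missing = vcs - intervals.chroms
    if missing:
        raise ValueError(
            f"variant chromosomes absent from intervals: {sorted(missing)}"
        )
    rec = intervals.records
    prio = {"intergenic": 0, "intronic": 1, "exonic": 2}
    rows = []
    for _, var in variants.iterrows():
        pos0 = int(var["pos"]) - 1
        chrom_rec = rec[rec["chrom"] == var["chrom"]]
        hit_genes: dict[str, str] = {}
        for _, iv in chrom_rec.iterrows():
            if iv["start"] - flank_bp <= pos0 < iv["end"] + flank_bp:
                gene = iv["gene_id"]
                inside = iv["start"] <= pos0 < iv["end"]
                if inside and iv["feature_class"] == "exon":
                    cls = "exonic"
                elif inside:
                    cls = "intronic"
                else:
                    cls = "intergenic"  # neighbored only through the flank
                if prio[cls] > prio.get(hit_genes.get(gene, ""), -1):
                    hit_genes[gene] = cls
        if hit_genes:
            for gene, cls in hit_genes.items():
                rows.append((var["id"], gene, cls))
        else:
            rows.append((var["id"], "", "intergenic"))
    return pd.DataFrame(rows, columns=["variant_id", "gene_id",
                                       "variant_class"])


def snp_gene_set(annotation: pd.DataFrame, kind: str,
                 stratum: str = "all") -> dict:
    """Collapse a variant-gene annotation into a snpGene set record."""

    with_gene = annotation[annotation["gene_id"] != ""]
    genes = sorted(set(with_gene["gene_id"]))
    support = {
        g: sorted(set(with_gene.loc[with_gene["gene_id"] == g, "variant_id"]))
        for g in genes
    }
    tally = annotation["variant_class"].value_counts().to_dict()
    return {"kind": kind, "stratum": stratum, "genes": genes,
            "support": support, "class_tally": tally}


def compare_snpgene_sets(sets: list) -> dict:
    """Pairwise Jaccard indices, global intersection, per-set specifics."""

    if len(sets) < 2:
        raise ValueError("need at least two snpGene sets")
    names = []
    for s in sets:
        if not s["genes"]:
            warnings.warn(f"snpGene set {s['kind']}/{s['stratum']} is empty",
                          stacklevel=2)
        names.append(f"{s['kind']}:{s['stratum']}")
    gene_sets = [set(s["genes"]) for s in sets]
    jac = pd.DataFrame(np.eye(len(sets)), index=names, columns=names)
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            union = gene_sets[i] | gene_sets[j]
            val = len(gene_sets[i] & gene_sets[j]) / len(union) if union else 0.0
            jac.iloc[i, j] = jac.iloc[j, i] = val
    common = set.intersection(*gene_sets) if gene_sets else set()
    specific = {
        names[i]: sorted(
            gene_sets[i] - set.union(*(gene_sets[:i] + gene_sets[i + 1:]))
        )
        for i in range(len(sets))
    }
    return {"jaccard": jac, "shared": sorted(common), "specific": specific}
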