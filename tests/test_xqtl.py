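"""xQTL scans against a normal-equations oracle, global chi-square
screens, and interval-based snpGene annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from osteomix.simulate import generate_genotypes
from osteomix.types import GeneIntervalSet, GenotypeMatrix, OmicsMatrix
from osteomix.xqtl import (
    annotate_snp_genes,
    compare_snpgene_sets,
    genotype_pcs,
    global_snp_test,
    qtl_scan,
    snp_gene_set,
)


def make_molecular(values):
    values = np.asarray(values, dtype=float)
    return OmicsMatrix(
        "metabolite",
        [f"f{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        np.exp(values),  # qtl_scan logs back to the analysis scale
    )


def ols_oracle(y, dose, cov):
    """Normal-equations OLS beta/se/p for the dosage coefficient."""

    A = np.column_stack([np.ones(len(dose)), dose, cov])
    beta_hat = np.linalg.solve(A.T @ A, A.T @ y)
    resid = y - A @ beta_hat
    dof = len(y) - A.shape[1]
    sigma2 = resid @ resid / dof
    cov_beta = sigma2 * np.linalg.inv(A.T @ A)
    se = np.sqrt(cov_beta[1, 1])
    t = beta_hat[1] / se
    return beta_hat[1], se, 2 * stats.t.sf(abs(t), dof)


class TestQtlScan:
    def test_matches_normal_equations_oracle(self, rng):
        n = 50
        g = generate_genotypes(n, 10, seed=1)
        cov = rng.standard_normal((n, 2))
        vals = rng.standard_normal((5, n))
        mol = make_molecular(vals)
        hits = qtl_scan(g, mol, cov, return_all=True)
        for _, row in hits.iterrows():
            j = list(g.variants["id"]).index(row["variant_id"])
            i = int(row["feature_id"][1:])
            beta, se, p = ols_oracle(vals[i], g.dosages[:, j], cov)
            assert row["beta"] == pytest.approx(beta, abs=1e-8)
            assert row["se"] == pytest.approx(se, abs=1e-8)
            assert row["p_value"] == pytest.approx(p, abs=1e-8)

    def test_feature_equal_to_dosage_perfect_fit(self):
        g = generate_genotypes(60, 3, seed=2)
        vals = np.vstack([g.dosages[:, 0], np.random.default_rng(0).random(60)])
        mol = make_molecular(vals)
        hits = qtl_scan(g, mol, p_threshold=1e-5)
        top = hits[(hits["variant_id"] == "rs000000")
                   & (hits["feature_id"] == "f0")]
        assert len(top) == 1
        assert top["beta"].iloc[0] == pytest.approx(1.0, abs=1e-8)
        assert top["p_value"].iloc[0] < 1e-30

    def test_invariant_to_covariate_rescaling(self, rng):
        n = 40
        g = generate_genotypes(n, 5, seed=3)
        cov = rng.standard_normal((n, 2))
        mol = make_molecular(rng.standard_normal((3, n)))
        a = qtl_scan(g, mol, cov, return_all=True)
        b = qtl_scan(g, mol, cov * np.array([10.0, 0.01]) + 5.0,
                     return_all=True)
        np.testing.assert_allclose(a["beta"], b["beta"], atol=1e-10)
        np.testing.assert_allclose(a["p_value"], b["p_value"], atol=1e-10)

    def test_missing_dosages_dropped_pairwise(self, rng):
        n = 60
        g = generate_genotypes(n, 2, seed=4, missing_rate=0.1)
        mol = make_molecular(rng.standard_normal((2, n)))
        hits = qtl_scan(g, mol, return_all=True)
        j = 0
        obs = ~np.isnan(g.dosages[:, j])
        vals = np.log(mol.values[0, obs])
        beta, se, p = ols_oracle(vals, g.dosages[obs, j],
                                 np.empty((obs.sum(), 0)))
        row = hits[(hits["variant_id"] == "rs000000")
                   & (hits["feature_id"] == "f0")].iloc[0]
        assert row["beta"] == pytest.approx(beta, abs=1e-8)

    def test_collinear_covariates_rejected(self, rng):
        n = 40
        g = generate_genotypes(n, 2, seed=5)
        mol = make_molecular(rng.standard_normal((2, n)))
        cov = np.column_stack([np.ones(n), np.ones(n) * 2])
        with pytest.raises(ValueError, match="collinear"):
            qtl_scan(g, mol, cov)

    def test_small_stratum_rejected(self, rng):
        g = generate_genotypes(30, 2, seed=6)
        mol = make_molecular(rng.standard_normal((2, 30)))
        with pytest.raises(ValueError):
            qtl_scan(g, mol, stratum_mask=np.arange(30) < 10)


class TestGlobalSnpTest:
    def test_identical_distributions_p_near_one(self):
        # same genotype composition in both groups
        col = np.array([0] * 30 + [1] * 40 + [2] * 30 +
                       [0] * 30 + [1] * 40 + [2] * 30, dtype=float)
        g = GenotypeMatrix(
            [f"s{i}" for i in range(200)],
            pd.DataFrame({"id": ["rs1"], "chrom": ["1"], "pos": [5],
                          "ref": ["A"], "alt": ["G"]}),
            col[:, None],
        )
        groups = np.array(["a"] * 100 + ["b"] * 100)
        out = global_snp_test(g, groups)
        assert out["p_value"].iloc[0] > 0.99

    def test_printed_two_by_two_table(self):
        # carriers vs non-carriers across two groups: [[10,20],[20,10]]
        col = np.array([0] * 10 + [1] * 20 + [0] * 20 + [1] * 10, dtype=float)
        g = GenotypeMatrix(
            [f"s{i}" for i in range(60)],
            pd.DataFrame({"id": ["rs1"], "chrom": ["1"], "pos": [5],
                          "ref": ["A"], "alt": ["G"]}),
            col[:, None],
        )
        groups = np.array(["a"] * 30 + ["b"] * 30)
        out = global_snp_test(g, groups)
        assert out["chi2"].iloc[0] == pytest.approx(6.667, abs=1e-3)
        assert out["p_value"].iloc[0] == pytest.approx(0.0098, abs=2e-4)

    def test_null_p_uniform(self):
        g = generate_genotypes(300, 400, seed=9)
        groups = np.array(["a", "b", "c"])[
            np.random.default_rng(1).integers(0, 3, 300)
        ]
        out = global_snp_test(g, groups)
        p = out["p_value"].dropna()
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_single_group_rejected(self):
        g = generate_genotypes(20, 2, seed=0)
        with pytest.raises(ValueError):
            global_snp_test(g, ["a"] * 20)


def toy_genotypes(positions, chrom="1"):
    n_var = len(positions)
    variants = pd.DataFrame({
        "id": [f"v{i}" for i in range(n_var)],
        "chrom": [chrom] * n_var,
        "pos": positions,
        "ref": ["A"] * n_var,
        "alt": ["G"] * n_var,
    })
    dosages = np.zeros((4, n_var))
    dosages[0, :] = 1
    return GenotypeMatrix(["s1", "s2", "s3", "s4"], variants, dosages)


class TestAnnotateSnpGenes:
    def _intervals(self):
        return GeneIntervalSet(pd.DataFrame({
            "chrom": ["1", "1"],
            "start": [100, 120],
            "end": [200, 140],
            "gene_id": ["GENE1", "GENE1"],
            "feature_class": ["gene", "exon"],
        }))

    def test_one_based_boundary_conversion(self):
        # pos=101 (1-based) -> 100 (0-based) is the first base inside
        g = toy_genotypes([101, 100])
        out = annotate_snp_genes(g, self._intervals(), flank_bp=0)
        classes = out.set_index("variant_id")["variant_class"].to_dict()
        assert classes["v0"] == "intronic"    # inside gene, outside exon
        assert classes["v1"] == "intergenic"  # pos-1 = 99 < start
        assert out.set_index("variant_id")["gene_id"]["v1"] == ""

    def test_nested_exon_takes_precedence(self):
        g = toy_genotypes([125])
        out = annotate_snp_genes(g, self._intervals(), flank_bp=0)
        assert out["variant_class"].iloc[0] == "exonic"

    def test_flank_reaches_neighbors(self):
        g = toy_genotypes([250])
        near = annotate_snp_genes(g, self._intervals(), flank_bp=100)
        far = annotate_snp_genes(g, self._intervals(), flank_bp=10)
        assert near["gene_id"].iloc[0] == "GENE1"
        assert near["variant_class"].iloc[0] == "intergenic"
        assert far["gene_id"].iloc[0] == ""

    def test_chromosome_mismatch_reported(self):
        g = toy_genotypes([150], chrom="chr9")
        with pytest.raises(ValueError, match="chr9"):
            annotate_snp_genes(g, self._intervals())


class TestCompareSnpGeneSets:
    def _set(self, genes, kind="xQTL", stratum="all"):
        return {"kind": kind, "stratum": stratum, "genes": list(genes),
                "support": {}, "class_tally": {}}

    def test_identical_sets_jaccard_one(self):
        out = compare_snpgene_sets(
            [self._set("ABC"), self._set("ABC", stratum="s2")]
        )
        assert out["jaccard"].iloc[0, 1] == 1.0

    def test_disjoint_and_partial_overlap(self):
        out = compare_snpgene_sets([
            self._set(["A", "B", "C"]),
            self._set(["B", "C", "D"], stratum="s2"),
            self._set(["X"], stratum="s3"),
        ])
        assert out["jaccard"].iloc[0, 1] == pytest.approx(0.5)
        assert out["jaccard"].iloc[0, 2] == 0.0
        assert out["specific"]["xQTL:s3"] == ["X"]

    def test_empty_set_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            compare_snpgene_sets([self._set([]), self._set("AB", stratum="b")])


def test_genotype_pcs_shape_and_determinism():
    g = generate_genotypes(100, 60, seed=3, missing_rate=0.02)
    pcs1 = genotype_pcs(g, 8)
    pcs2 = genotype_pcs(g, 8)
    assert pcs1.shape == (100, 8)
    np.testing.assert_allclose(pcs1, pcs2)
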