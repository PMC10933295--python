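"""DLSF core: self-expression solvers against oracles, fusion algebra,
spectral clustering, k selection, and training determinism."""

import numpy as np
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from osteomix.dlsf import (
    DlsfConfig,
    SubtypeAssignment,
    fuse_affinities,
    nonnegative_self_expression,
    ridge_self_expression,
    select_k,
    spectral_cluster,
    train_dlsf,
)
from osteomix.types import PhenotypeTable

import pandas as pd


def per_row_ridge_oracle(Z, lam):
    """Brute per-row ridge solve with the i-th sample excluded."""

    n = Z.shape[0]
    C = np.zeros((n, n))
    for i in range(n):
        idx = [j for j in range(n) if j != i]
        G = Z[idx] @ Z[idx].T
        C[i, idx] = np.linalg.solve(G + lam * np.eye(n - 1), Z[idx] @ Z[i])
    return C


class TestSelfExpression:
    def test_closed_form_matches_per_row_oracle(self, rng):
        Z = rng.standard_normal((25, 6))
        C = ridge_self_expression(Z, 0.7)
        np.testing.assert_allclose(C, per_row_ridge_oracle(Z, 0.7), atol=1e-10)
        assert np.abs(np.diag(C)).max() == 0.0

    def test_nonnegative_solution_is_feasible_and_no_worse(self, rng):
        Z = rng.standard_normal((20, 5))
        lam = 2.0
        C = nonnegative_self_expression(Z, lam)
        assert (C >= 0).all() and np.abs(np.diag(C)).max() == 0.0

        def objective(C):
            return np.sum((Z - C @ Z) ** 2) + lam * np.sum(C ** 2)

        # optimal among nonnegative solutions: no better than unconstrained,
        # and clipping the unconstrained optimum cannot beat it
        unconstrained = ridge_self_expression(Z, lam)
        clipped = np.clip(unconstrained, 0, None)
        assert objective(C) >= objective(unconstrained) - 1e-9
        assert objective(C) <= objective(clipped) + 1e-9

    def test_two_orthogonal_subspaces_block_diagonal(self, rng):
        # samples on two orthogonal 3-d subspaces of R^12
        basis1 = np.linalg.qr(rng.standard_normal((12, 3)))[0]
        basis2 = np.linalg.qr(rng.standard_normal((12, 3)))[0]
        basis2 -= basis1 @ (basis1.T @ basis2)
        basis2 = np.linalg.qr(basis2)[0]
        Z = np.vstack([
            rng.standard_normal((20, 3)) @ basis1.T,
            rng.standard_normal((20, 3)) @ basis2.T,
        ])
        C = ridge_self_expression(Z, 1e-3)
        A = np.abs(C) + np.abs(C).T
        off = A[:20, 20:].sum() * 2
        assert off / A.sum() < 0.05

    def test_positive_penalty_required(self, rng):
        with pytest.raises(ValueError):
            ridge_self_expression(rng.standard_normal((5, 2)), 0.0)


class TestFuseAffinities:
    def test_single_matrix_normalized_symmetrization(self, rng):
        C = rng.standard_normal((10, 10))
        np.fill_diagonal(C, 0)
        S = fuse_affinities([C])
        expected = np.abs(C) + np.abs(C).T
        np.fill_diagonal(expected, 0)
        np.testing.assert_allclose(S, expected / expected.max())

    def test_mean_of_identical_inputs_idempotent(self, rng):
        C = rng.standard_normal((8, 8))
        np.testing.assert_allclose(fuse_affinities([C, C]),
                                   fuse_affinities([C]))

    def test_symmetric_nonnegative_for_arbitrary_inputs(self, rng):
        mats = [rng.standard_normal((12, 12)) for _ in range(3)]
        S = fuse_affinities(mats)
        assert (S >= 0).all()
        np.testing.assert_allclose(S, S.T)
        assert np.abs(np.diag(S)).max() == 0.0

    def test_block_structure_preserved(self):
        C = np.zeros((6, 6))
        C[:3, :3] = 0.5
        C[3:, 3:] = 0.5
        np.fill_diagonal(C, 0)
        S = fuse_affinities([C, C.copy()])
        assert S[:3, 3:].sum() == 0.0


class TestSpectralCluster:
    def test_ideal_two_block_recovery(self):
        S = np.zeros((40, 40))
        S[:18, :18] = 1.0
        S[18:, 18:] = 1.0
        np.fill_diagonal(S, 0)
        assign = spectral_cluster(S, 2, seed=0)
        truth = [0] * 18 + [1] * 22
        assert adjusted_rand_score(truth, assign.labels) == 1.0
        assert set(assign.labels) == {1, 2}

    def test_k_one_rejected(self):
        with pytest.raises(ValueError):
            spectral_cluster(np.ones((5, 5)), 1)

    def test_too_many_components_reported(self):
        S = np.zeros((9, 9))
        for b in range(3):
            S[3 * b: 3 * b + 3, 3 * b: 3 * b + 3] = 1.0
        np.fill_diagonal(S, 0)
        with pytest.raises(ValueError, match="components"):
            spectral_cluster(S, 2)

    def test_labels_deterministic(self, rng):
        S = rng.random((30, 30))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 0)
        a = spectral_cluster(S, 3, seed=4)
        b = spectral_cluster(S.copy(), 3, seed=4)
        np.testing.assert_array_equal(a.labels, b.labels)


def _noise_phenotypes(n, rng, n_cols=6):
    table = pd.DataFrame(
        {f"pheno{i}": rng.standard_normal(n) for i in range(n_cols)},
        index=[f"S{i:04d}" for i in range(n)],
    )
    table["group"] = "osteoporosis"
    return PhenotypeTable(table)


class TestSelectK:
    def test_two_ideal_blocks_select_two(self, rng):
        # exactly two ideal blocks: k >= 3 can only subdivide a block, so
        # the block-aligned phenotype stays associated at every k and the
        # association-count tie resolves to the smallest k
        n = 60
        S = np.zeros((n, n))
        S[:30, :30] = 1.0
        S[30:, 30:] = 1.0
        np.fill_diagonal(S, 0)
        pheno = _noise_phenotypes(n, rng, n_cols=0)
        pheno.table["pheno0"] = np.r_[np.zeros(30), np.ones(30)] \
            + 0.1 * rng.standard_normal(n)
        k_star, assign, report = select_k(S, (2, 3, 4), pheno)
        assert k_star == 2
        assert assign.k == 2

    def test_singleton_range(self, rng):
        S = rng.random((20, 20))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 0)
        k_star, _, report = select_k(S, (2,), _noise_phenotypes(20, rng))
        assert k_star == 2 and len(report) == 1

    def test_empty_range_rejected(self, rng):
        with pytest.raises(ValueError):
            select_k(np.ones((4, 4)), (), _noise_phenotypes(4, rng))


class TestTrainDlsf:
    def test_training_deterministic(self, rng):
        X = rng.standard_normal((30, 20))
        cfg = DlsfConfig(epochs_pretrain=20, epochs_joint=20, seed=3)
        _, C1, h1 = train_dlsf([X], cfg)
        _, C2, h2 = train_dlsf([X.copy()], cfg)
        np.testing.assert_array_equal(C1["0"], C2["0"])
        assert h1["0"]["loss"].iloc[-1] == h2["0"]["loss"].iloc[-1]

    def test_reconstruction_loss_decreases(self, rng):
        X = rng.standard_normal((40, 25))
        cfg = DlsfConfig(epochs_pretrain=80, epochs_joint=0, seed=0)
        _, _, hist = train_dlsf([X], cfg)
        losses = hist["0"]["loss_rec"]
        assert losses.iloc[-1] < 0.5 * losses.iloc[0]

    def test_gradients_match_finite_differences(self, rng):
        # spot-check the hand-written backprop on a tiny net
        from osteomix.dlsf import _forward, _grads, _init_params, _losses

        X = rng.standard_normal((6, 4))
        cfg = DlsfConfig(latent_dim=2, hidden_dim=3)
        P = _init_params(4, 3, 2, rng)
        C = rng.random((6, 6)) * 0.1
        np.fill_diagonal(C, 0)
        ImC = np.eye(6) - C
        M = ImC.T @ ImC

        def loss_fn():
            H1, Z, H2, Xh = _forward(X, P)
            l_rec, l_se, _ = _losses(X, Z, Xh, C, cfg)
            return l_rec + l_se

        H1, Z, H2, Xh = _forward(X, P)
        g = _grads(X, P, H1, Z, H2, Xh, M, cfg)
        eps = 1e-6
        for key in ("W1", "W2", "W3", "W4"):
            idx = (0, 0)
            P[key][idx] += eps
            up = loss_fn()
            P[key][idx] -= 2 * eps
            down = loss_fn()
            P[key][idx] += eps
            assert g[key][idx] == pytest.approx((up - down) / (2 * eps),
                                                rel=1e-4, abs=1e-8)

    def test_latent_dim_exceeding_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="latent_dim"):
            train_dlsf([rng.standard_normal((8, 5))],
                       DlsfConfig(latent_dim=16))

    def test_dlsf_at_least_as_accurate_as_raw_kmeans_on_subspace_data(self, rng):
        # zero-mean clusters on two orthogonal 2-d subspaces of R^30:
        # no centroid separation for k-means, but linearly separable
        # subspace structure for self-expression
        n_half, p = 25, 30
        basis1 = np.linalg.qr(rng.standard_normal((p, 2)))[0]
        basis2 = np.linalg.qr(rng.standard_normal((p, 2)))[0]
        basis2 -= basis1 @ (basis1.T @ basis2)
        basis2 = np.linalg.qr(basis2)[0]
        X = np.vstack([
            (3.0 * rng.standard_normal((n_half, 2))) @ basis1.T,
            (3.0 * rng.standard_normal((n_half, 2))) @ basis2.T,
        ]) + 0.05 * rng.standard_normal((2 * n_half, p))
        truth = np.array([0] * n_half + [1] * n_half)
        cfg = DlsfConfig(epochs_pretrain=80, epochs_joint=80, seed=0,
                         latent_dim=8)
        _, C, _ = train_dlsf([X], cfg)
        assign = spectral_cluster(fuse_affinities([C["0"]]), 2, seed=0)
        ari_dlsf = adjusted_rand_score(truth, assign.labels)
        km = KMeans(2, n_init=10, random_state=0).fit_predict(X)
        ari_km = adjusted_rand_score(truth, km)
        assert ari_dlsf >= ari_km - 1e-9
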