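"""Deep latent space fusion (DLSF) subtyping.

Each modality gets a two-layer autoencoder whose bottleneck Z feeds a
self-expression layer: every sample's latent vector is approximated as a
linear combination of the *other* samples' latents, Z ~ C Z with
diag(C) = 0.  The joint objective per modality is

    lambda_rec ||X - Dec(Z)||^2 + lambda_se ||Z - C Z||^2
        + lambda_reg ||C||^2,

trained in two phases: reconstruction-only pretraining, then joint
training where C is refreshed by its exact closed-form ridge solution
(zero-diagonal least squares regression, see
:func:`ridge_self_expression`) while the network weights take Adam steps
against the full objective.  The per-modality coefficient matrices are
fused into a single symmetric sample affinity, which normalized-cut
spectral clustering partitions into candidate subtypes.

Everything is full-batch NumPy and deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from .transforms import standardize, to_analysis_scale
from .types import OmicsMatrix


@dataclass
class DlsfConfig:
    latent_dim: int = 16
    hidden_dim: int = 64
    epochs_pretrain: int = 150
    epochs_joint: int = 150
    learning_rate: float = 1e-3
    lambda_rec: float = 1.0
    lambda_se: float = 1.0
    lambda_reg: float = 1.0
    nonnegative: bool = True
    c_update_every: int = 25
    k_range: tuple = (2, 3, 4)
    balance_floor: float = 0.7
    kmeans_restarts: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        for w in ("lambda_rec", "lambda_se", "lambda_reg"):
            if getattr(self, w) < 0:
                raise ValueError(f"{w} must be nonnegative")
        if not self.k_range:
            raise ValueError("k_range must be non-empty")


@dataclass
class SubtypeAssignment:
    sample_ids: list
    labels: np.ndarray  # 1..k
    k: int
    affinity: np.ndarray
    quality: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "subtype": self.labels}
        ).set_index("sample_id")


# ---------------------------------------------------------------------------
# self-expression


def ridge_self_expression(Z: np.ndarray, lam: float) -> np.ndarray:
    """Exact solution of min_C ||Z - CZ||^2 + lam ||C||^2, diag(C)=0.

    With G = Z Z' and A = (G + lam I)^-1, KKT elimination of the diagonal
    constraint gives C[i, j] = -A[i, j] / A[i, i] for i != j.
    """

    if lam <= 0:
        raise ValueError("ridge penalty must be positive")
    n = Z.shape[0]
    G = Z @ Z.T
    A = np.linalg.inv(G + lam * np.eye(n))
    C = -A / np.diag(A)[:, None]
    np.fill_diagonal(C, 0.0)
    return C


def nonnegative_self_expression(Z: np.ndarray, lam: float) -> np.ndarray:
    """min_C ||Z - CZ||^2 + lam ||C||^2 with C >= 0 and diag(C)=0.

    Solved row-wise by nonnegative least squares on the ridge-augmented
    system.  The sign constraint is what makes the affinity meaningful
    for mean-shifted clusters: two clusters centered at +-mu span the
    *same* linear subspace, so unconstrained coefficients express a
    sample equally well with either cluster (with flipped signs) and
    |C| carries no block structure; nonnegative coefficients cannot use
    the antipodal cluster.  ``lam`` should be on the scale of the latent
    energy (see :func:`train_dlsf`, which scales it by mean ||z_i||^2),
    which drives C toward a thresholded inner-product kernel.
    """

    from scipy.optimize import nnls

    if lam <= 0:
        raise ValueError("ridge penalty must be positive")
    n = Z.shape[0]
    C = np.zeros((n, n))
    sq = np.sqrt(lam)
    eye = sq * np.eye(n - 1)
    for i in range(n):
        idx = np.arange(n) != i
        A = np.vstack([Z[idx].T, eye])
        b = np.concatenate([Z[i], np.zeros(n - 1)])
        c, _ = nnls(A, b)
        C[i, idx] = c
    return C


# ---------------------------------------------------------------------------
# autoencoder in plain NumPy


class _Adam:
    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mh = self.m[k] / (1 - b1 ** self.t)
            vh = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + eps)


def _init_params(p: int, h: int, d: int, rng: np.random.Generator) -> dict:
    def glorot(fan_in, fan_out):
        s = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-s, s, size=(fan_in, fan_out))

    return {
        "W1": glorot(p, h), "b1": np.zeros(h),
        "W2": glorot(h, d), "b2": np.zeros(d),
        "W3": glorot(d, h), "b3": np.zeros(h),
        "W4": glorot(h, p), "b4": np.zeros(p),
    }


def _forward(X: np.ndarray, P: dict):
    H1 = np.tanh(X @ P["W1"] + P["b1"])
    Z = H1 @ P["W2"] + P["b2"]
    H2 = np.tanh(Z @ P["W3"] + P["b3"])
    Xh = H2 @ P["W4"] + P["b4"]
    return H1, Z, H2, Xh


def _losses(X, Z, Xh, C, cfg: DlsfConfig):
    n = X.shape[0]
    l_rec = cfg.lambda_rec * np.sum((X - Xh) ** 2) / n
    if C is None:
        return l_rec, 0.0, 0.0
    R = Z - C @ Z
    l_se = cfg.lambda_se * np.sum(R ** 2) / n
    l_reg = cfg.lambda_reg * np.sum(C ** 2) / n
    return l_rec, l_se, l_reg


def _grads(X, P, H1, Z, H2, Xh, M, cfg: DlsfConfig) -> dict:
    """Full-batch gradients; M = (I-C)'(I-C) or None during pretraining."""

    n = X.shape[0]
    dXh = cfg.lambda_rec * 2.0 * (Xh - X) / n
    g = {}
    g["W4"] = H2.T @ dXh
    g["b4"] = dXh.sum(axis=0)
    dH2 = dXh @ P["W4"].T
    dA3 = dH2 * (1.0 - H2 ** 2)
    g["W3"] = Z.T @ dA3
    g["b3"] = dA3.sum(axis=0)
    dZ = dA3 @ P["W3"].T
    if M is not None:
        dZ = dZ + cfg.lambda_se * 2.0 * (M @ Z) / n
    g["W2"] = H1.T @ dZ
    g["b2"] = dZ.sum(axis=0)
    dH1 = dZ @ P["W2"].T
    dA1 = dH1 * (1.0 - H1 ** 2)
    g["W1"] = X.T @ dA1
    g["b1"] = dA1.sum(axis=0)
    return g


def _solve_c(Z: np.ndarray, config: DlsfConfig) -> np.ndarray:
    """Refresh the self-expression matrix for the current latent.

    The ridge penalty is lambda_reg/lambda_se scaled by the mean latent
    energy, so the strength of C's shrinkage tracks the (changing) scale
    of Z during training.
    """

    lam = config.lambda_reg / max(config.lambda_se, 1e-12)
    lam = lam * max(float((Z ** 2).sum(axis=1).mean()), 1e-12)
    if config.nonnegative:
        return nonnegative_self_expression(Z, lam)
    return ridge_self_expression(Z, lam)


def _prepare_input(modality) -> np.ndarray:
    """OmicsMatrix -> standardized samples-x-features array."""

    if isinstance(modality, OmicsMatrix):
        X = to_analysis_scale(modality)       # features x samples
        return standardize(X, axis=1).T
    X = np.asarray(modality, dtype=float)     # samples x features
    return standardize(X, axis=0)


def train_dlsf(omics: list, config: DlsfConfig | None = None):
    """Train per-modality autoencoders with self-expression.

    ``omics`` is a list of :class:`OmicsMatrix` (transformed to each
    modality's analysis scale and z-scored internally) or of raw
    samples-x-features arrays.  Returns ``(latents, selfexpr, history)``
    keyed by modality name (or position for raw arrays).
    """

    config = config or DlsfConfig()
    if not omics:
        raise ValueError("need at least one modality")
    latents: dict = {}
    selfexpr: dict = {}
    history: dict = {}
    for idx, modality in enumerate(omics):
        name = modality.modality if isinstance(modality, OmicsMatrix) else str(idx)
        X = _prepare_input(modality)
        n, p = X.shape
        if n < config.latent_dim:
            raise ValueError(
                f"{name}: n_samples={n} below latent_dim={config.latent_dim}"
            )
        h = min(config.hidden_dim, p)
        rng = np.random.default_rng([idx, int(config.seed)])
        P = _init_params(p, h, config.latent_dim, rng)
        opt = _Adam(P, config.learning_rate)
        C = None
        M = None
        records = []
        total = config.epochs_pretrain + config.epochs_joint
        for epoch in range(total):
            joint = epoch >= config.epochs_pretrain
            H1, Z, H2, Xh = _forward(X, P)
            if joint and (
                C is None
                or (epoch - config.epochs_pretrain) % config.c_update_every == 0
            ):
                C = _solve_c(Z, config)
                ImC = np.eye(n) - C
                M = ImC.T @ ImC
            l_rec, l_se, l_reg = _losses(X, Z, Xh, C if joint else None, config)
            loss = l_rec + l_se + l_reg
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"{name}: non-finite loss at epoch {epoch} "
                    f"(rec={l_rec:.3g}, se={l_se:.3g}, reg={l_reg:.3g})"
                )
            records.append((epoch, "joint" if joint else "pretrain",
                            l_rec, l_se, l_reg, loss))
            g = _grads(X, P, H1, Z, H2, Xh, M if joint else None, config)
            opt.step(P, g)
        _, Z, _, _ = _forward(X, P)
        C = _solve_c(Z, config) if config.lambda_se > 0 else np.zeros((n, n))
        latents[name] = Z
        selfexpr[name] = C
        history[name] = pd.DataFrame(
            records,
            columns=["epoch", "phase", "loss_rec", "loss_se", "loss_reg", "loss"],
        )
    return latents, selfexpr, history


# ---------------------------------------------------------------------------
# fusion and clustering


def fuse_affinities(c_list: list) -> np.ndarray:
    """Average the unit-max-normalized symmetrized |C| matrices."""

    if not c_list:
        raise ValueError("need at least one self-expression matrix")
    n = c_list[0].shape[0]
    S = np.zeros((n, n))
    for C in c_list:
        if C.shape != (n, n):
            raise ValueError("self-expression matrices differ in size")
        A = np.abs(C) + np.abs(C).T
        np.fill_diagonal(A, 0.0)
        peak = A.max()
        if peak > 0:
            A = A / peak
        S += A
    S /= len(c_list)
    return S


def spectral_cluster(S: np.ndarray, k: int, sample_ids=None,
                     seed: int = 0, restarts: int = 50) -> SubtypeAssignment:
    """Normalized-cut spectral clustering of a fused affinity.

    Symmetric-normalized Laplacian, bottom-k eigenvectors, row
    normalization, then k-means with ``restarts`` seeded restarts.
    Labels are canonicalized to first-appearance order, so output is
    invariant to k-means' internal label permutation.
    """

    n = S.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("k exceeds number of samples")
    n_comp, comp = connected_components(S > 0, directed=False)
    if n_comp > k:
        sizes = np.bincount(comp)
        raise ValueError(
            f"affinity graph has {n_comp} components (sizes {sizes.tolist()}) "
            f"but only k={k} clusters requested"
        )
    deg = S.sum(axis=1)
    deg = np.where(deg == 0, 1.0, deg)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    L = np.eye(n) - d_inv_sqrt[:, None] * S * d_inv_sqrt[None, :]
    L = (L + L.T) / 2.0
    _, vecs = eigh(L, subset_by_index=(0, k - 1))
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms = np.where(norms == 0, 1.0, norms)
    U = vecs / norms
    km = KMeans(n_clusters=k, n_init=restarts, random_state=int(seed))
    raw = km.fit_predict(U)
    labels = _canonicalize(raw)
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(n)]
    return SubtypeAssignment(list(sample_ids), labels, k, S)


def _canonicalize(raw: np.ndarray) -> np.ndarray:
    mapping: dict = {}
    out = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping) + 1
        out[i] = mapping[r]
    return out


def select_k(S: np.ndarray, k_range, phenotypes, sample_ids=None,
             balance_floor: float = 0.7, alpha: float = 0.05,
             seed: int = 0, phenotype_columns=None):
    """Pick the cluster count the way the subtype evaluation prescribes.

    For each k, cluster and compute the balance index and the count of
    clinical phenotypes associated at P < alpha; k* maximizes the
    association count among k with balance >= ``balance_floor`` (ties go
    to the smaller k).  If no k clears the floor, the most balanced k is
    returned with a flag in the report.
    """

    from .evaluate import balance_index, phenotype_association_count

    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValueError("empty k_range")
    rows = []
    assignments = {}
    for k in k_range:
        assign = spectral_cluster(S, k, sample_ids=sample_ids, seed=seed)
        assignments[k] = assign
        bal = balance_index(assign.labels, k=k)
        assoc, _ = phenotype_association_count(
            assign.labels, phenotypes, alpha=alpha, columns=phenotype_columns
        )
        assign.quality = {"balance": bal, "association_count": assoc}
        rows.append((k, bal, assoc, bal >= balance_floor))
    report = pd.DataFrame(
        rows, columns=["k", "balance", "association_count", "balanced"]
    )
    ok = report[report["balanced"]]
    if ok.empty:
        k_star = int(report.sort_values(
            ["balance", "k"], ascending=[False, True]).iloc[0]["k"])
        report.attrs["note"] = "no k met the balance floor"
    else:
        best = ok.sort_values(
            ["association_count", "k"], ascending=[False, True]
        ).iloc[0]
        k_star = int(best["k"])
    return k_star, assignments[k_star], report


def subtype_cohort(omics: list, phenotypes, config: DlsfConfig | None = None,
                   population_mask=None, sample_ids=None,
                   phenotype_columns=None):
    """End-to-end DLSF subtyping of (a stratum of) a cohort.

    ``population_mask`` restricts clustering to a subset of samples (the
    default use clusters the osteoporosis group only).  Returns
    ``(assignment, report, history)``.
    """

    config = config or DlsfConfig()
    if population_mask is not None:
        mask = np.asarray(population_mask, dtype=bool)
        omics = [
            m.subset_samples([s for s, keep in zip(m.sample_ids, mask) if keep])
            if isinstance(m, OmicsMatrix) else np.asarray(m)[mask]
            for m in omics
        ]
        if sample_ids is not None:
            sample_ids = [s for s, keep in zip(sample_ids, mask) if keep]
        phenotypes = phenotypes.subset_samples(
            [s for s in phenotypes.sample_ids
             if sample_ids is None or s in set(sample_ids)]
        ) if phenotypes is not None else None
    if sample_ids is None and isinstance(omics[0], OmicsMatrix):
        sample_ids = list(omics[0].sample_ids)
    if phenotypes is not None and isinstance(omics[0], OmicsMatrix):
        phenotypes = phenotypes.subset_samples(omics[0].sample_ids)
    _, selfexpr, history = train_dlsf(omics, config)
    S = fuse_affinities(list(selfexpr.values()))
    if phenotypes is None:
        assign = spectral_cluster(S, min(config.k_range), sample_ids, config.seed)
        return assign, None, history
    _, assign, report = select_k(
        S, config.k_range, phenotypes, sample_ids,
        balance_floor=config.balance_floor, seed=config.seed,
        phenotype_columns=phenotype_columns,
    )
    return assign, report, history
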