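"""Differential association matrix (DAM) analysis and M3S selection.

Stratum-specific Spearman association matrices between two feature sets
(two modalities, or a modality against clinical phenotypes) are compared
across subtypes with the Fisher z test,

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)),

flagging rewired pairs and in particular sign flips (opposite-sign
correlations with |rho| above a report threshold in both strata, the
pattern highlighted between e.g. a microbe and a metabolite in the two
clinical subtypes).  Multi-modal molecular signatures (M3S) are selected
per modality by intersecting high-|weight| features from a
stemness-like one-class regression on a reference stratum with the
Wilcoxon-significant features of the subtype contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import bh_qvalues
from .transforms import to_analysis_scale
from .types import OmicsMatrix

SIGN_FLIP_RHO = 0.3  # both-strata magnitude needed to call a sign flip


@dataclass
class AssociationMatrix:
    row_ids: list
    col_ids: list
    stratum: str
    rho: np.ndarray
    p: np.ndarray
    n_stratum: int


def _rows(values, ids=None):
    """Accept an OmicsMatrix (analysis scale) or raw features-x-samples."""

    if isinstance(values, OmicsMatrix):
        return to_analysis_scale(values), list(values.feature_ids)
    arr = np.asarray(values, dtype=float)
    if ids is None:
        ids = [f"f{i}" for i in range(arr.shape[0])]
    return arr, list(ids)


def association_matrix(X, Y, stratum_mask, stratum: str = "",
                       row_ids=None, col_ids=None) -> AssociationMatrix:
    """Pairwise Spearman rho/p between rows of X and rows of Y in a stratum.

    Entries involving a stratum-constant feature are set to NaN and
    flagged with a warning.
    """

    mask = np.asarray(stratum_mask, dtype=bool)
    n = int(mask.sum())
    if n < 5:
        raise ValueError("stratum needs at least 5 samples")
    xv, xids = _rows(X, row_ids)
    yv, yids = _rows(Y, col_ids)
    xv, yv = xv[:, mask], yv[:, mask]
    rx = np.apply_along_axis(stats.rankdata, 1, xv)
    ry = np.apply_along_axis(stats.rankdata, 1, yv)
    rx_sd = rx.std(axis=1)
    ry_sd = ry.std(axis=1)
    const_x = rx_sd == 0
    const_y = ry_sd == 0
    if const_x.any() or const_y.any():
        warnings.warn("constant features in stratum; entries set to NaN",
                      stacklevel=2)
    rxc = (rx - rx.mean(axis=1, keepdims=True))
    ryc = (ry - ry.mean(axis=1, keepdims=True))
    denom = np.outer(np.where(rx_sd == 0, 1, rx_sd),
                     np.where(ry_sd == 0, 1, ry_sd)) * n
    rho = (rxc @ ryc.T) / denom
    rho[const_x, :] = np.nan
    rho[:, const_y] = np.nan
    rho = np.clip(rho, -1.0, 1.0)
    # asymptotic t-based p-values
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    p[np.isnan(rho)] = np.nan
    return AssociationMatrix(xids, yids, stratum, rho, p, n)


def differential_association(a1: AssociationMatrix,
                             a2: AssociationMatrix) -> pd.DataFrame:
    """Fisher-z rewiring statistics for every feature pair.

    Requires the two matrices to cover identical feature sets on disjoint
    strata.  ``delta = rho1 - rho2``; ``sign_flip`` marks opposite-sign
    correlations with both magnitudes >= the report threshold.
    """

    if a1.row_ids != a2.row_ids or a1.col_ids != a2.col_ids:
        raise ValueError("association matrices cover different feature sets")
    n1, n2 = a1.n_stratum, a2.n_stratum
    if min(n1, n2) <= 3:
        raise ValueError("Fisher z needs more than 3 samples per stratum")
    r1 = np.clip(a1.rho, -0.999999, 0.999999)
    r2 = np.clip(a2.rho, -0.999999, 0.999999)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    flip = (a1.rho * a2.rho < 0) & (np.abs(a1.rho) >= SIGN_FLIP_RHO) \
        & (np.abs(a2.rho) >= SIGN_FLIP_RHO)
    rows, cols = np.meshgrid(
        np.arange(len(a1.row_ids)), np.arange(len(a1.col_ids)), indexing="ij"
    )
    out = pd.DataFrame(
        {
            "row_feature": np.asarray(a1.row_ids)[rows.ravel()],
            "col_feature": np.asarray(a1.col_ids)[cols.ravel()],
            "rho1": a1.rho.ravel(),
            "rho2": a2.rho.ravel(),
            "delta": (a1.rho - a2.rho).ravel(),
            "z": z.ravel(),
            "p_rewire": p.ravel(),
            "sign_flip": flip.ravel(),
        }
    )
    valid = ~out["p_rewire"].isna()
    q = np.full(len(out), np.nan)
    if valid.any():
        q[valid.to_numpy()] = bh_qvalues(out.loc[valid, "p_rewire"].to_numpy())
    out["q_rewire"] = q
    return out


# ---------------------------------------------------------------------------
# stemness-like weighting and M3S selection


def stemness_like_weights(reference, full, ridge: float = 1e-3):
    """One-class regression weights from a reference stratum.

    Fits ridge least squares of a constant one-target on the reference
    samples' analysis-scale profiles (OCLR-style one-class weighting):
    w = (X X' + lam I)^-1 X 1, normalized to unit length, so w points
    along the regularized mean profile of the reference stratum.  The
    per-sample index is the Spearman correlation between w and the
    sample's feature vector; rank-based scoring makes the index
    invariant to monotone rescaling of a sample's values.

    ``reference`` and ``full`` are OmicsMatrix objects (reference samples
    must be a subset of full) or raw features-x-samples arrays.  Returns
    ``(weights Series, index Series over full samples)``.
    """

    ref_vals, fids = _rows(reference)
    full_vals, fids_full = _rows(full)
    if fids != fids_full:
        raise ValueError("reference and full matrices differ in features")
    if ref_vals.shape[1] < 5:
        raise ValueError("reference stratum needs at least 5 samples")
    X = ref_vals                      # features x ref samples
    p = X.shape[0]
    # scale-free ridge: penalty relative to the mean feature energy
    lam = ridge * max(float(np.mean(np.sum(X * X, axis=1))), 1e-12)
    w = np.linalg.solve(X @ X.T + lam * np.eye(p), X.sum(axis=1))
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("degenerate reference stratum: zero weight vector")
    w = w / norm
    sample_ids = (
        full.sample_ids if isinstance(full, OmicsMatrix)
        else [f"s{i}" for i in range(full_vals.shape[1])]
    )
    index = np.array([
        stats.spearmanr(w, full_vals[:, j]).statistic
        for j in range(full_vals.shape[1])
    ])
    return (
        pd.Series(w, index=fids, name="weight"),
        pd.Series(index, index=sample_ids, name="stemness_index"),
    )


def select_m3s(weights: dict, differential: dict, top_q: dict,
               alpha: float = 0.05) -> pd.DataFrame:
    """Intersect top-|weight| features with Wilcoxon-significant ones.

    ``weights`` maps modality -> weight Series; ``differential`` maps
    modality -> wilcoxon_screen table; ``top_q`` maps modality -> the
    number of top-|w| features eligible.  If an intersection is empty the
    modality falls back to its top-q features by |weight| with a warning.
    Output ordering (by modality, then descending |weight|, then feature
    ID) is deterministic.
    """

    frames = []
    for modality in sorted(weights):
        w = weights[modality]
        q = int(top_q[modality])
        ranked = w.reindex(
            w.abs().sort_values(ascending=False, kind="mergesort").index
        )
        top = ranked.iloc[:q]
        diff = differential[modality]
        significant = set(diff.loc[diff["p_value"] < alpha, "feature_id"])
        chosen = top[top.index.isin(significant)]
        if chosen.empty:
            warnings.warn(
                f"{modality}: no overlap between top-{q} weights and the "
                "differential screen; falling back to weights alone",
                stacklevel=2,
            )
            chosen = top
        frame = pd.DataFrame(
            {
                "modality": modality,
                "feature_id": chosen.index,
                "weight": chosen.to_numpy(),
            }
        )
        frame["rank"] = np.arange(1, len(frame) + 1)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
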