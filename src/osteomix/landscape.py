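"""Molecular-landscape statistics: differential screens, cross-modality
RV indices and per-group co-expression networks.

The differential screen is the two-sided Wilcoxon rank-sum test per
feature at raw P < 0.05 (the "discriminative fraction" of a modality is
the fraction of its features passing the screen); Benjamini-Hochberg
q-values are reported alongside but the screen itself is uncorrected.
Microbiota correlations are computed after a CLR transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .transforms import to_analysis_scale
from .types import OmicsMatrix


@dataclass
class DifferentialResult:
    feature_id: str
    contrast: str
    statistic: float
    p_value: float
    direction: int  # sign of the location shift (group1 - group2)


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""

    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(ranked, 1.0)
    return q


def wilcoxon_screen(matrix: OmicsMatrix, groups, alpha: float = 0.05,
                    contrast: str = "") -> tuple[pd.DataFrame, float]:
    """Per-feature two-sided rank-sum test between two sample groups.

    ``groups`` is a boolean or 0/1 vector over samples (True = group 1).
    Uses the exact null distribution when both groups have <= 25 samples
    and the data are tie-free, otherwise the tie-corrected normal
    approximation.  Returns (results table, discriminative fraction).
    """

    mask = np.asarray(groups, dtype=bool)
    n1, n2 = int(mask.sum()), int((~mask).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    x = matrix.values[:, mask]
    y = matrix.values[:, ~mask]
    rows = []
    for i, fid in enumerate(matrix.feature_ids):
        xi, yi = x[i], y[i]
        has_ties = np.unique(np.concatenate([xi, yi])).size < (n1 + n2)
        method = "exact" if (max(n1, n2) <= 25 and not has_ties) else "asymptotic"
        if np.ptp(np.concatenate([xi, yi])) == 0:
            stat, p = n1 * n2 / 2.0, 1.0
        else:
            res = stats.mannwhitneyu(xi, yi, alternative="two-sided", method=method)
            stat, p = float(res.statistic), float(res.pvalue)
        direction = int(np.sign(np.median(xi) - np.median(yi)))
        rows.append((fid, contrast, stat, p, direction))
    table = pd.DataFrame(
        rows, columns=["feature_id", "contrast", "statistic", "p_value", "direction"]
    )
    table["q_value"] = bh_qvalues(table["p_value"].to_numpy())
    frac = float((table["p_value"] < alpha).mean())
    return table, frac


def rv_coefficient(X: np.ndarray, Y: np.ndarray) -> float:
    """RV index between two sample-by-feature matrices.

    RV = trace(XX'YY') / sqrt(trace((XX')^2) trace((YY')^2)) on
    column-centered matrices; 1 iff the two configurations agree up to
    rotation/scaling, 0 iff their sample configurations are orthogonal.
    """

    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must share the sample dimension")
    Xc = X - X.mean(axis=0, keepdims=True)
    Yc = Y - Y.mean(axis=0, keepdims=True)
    Sx = Xc @ Xc.T
    Sy = Yc @ Yc.T
    denom = np.sqrt((Sx * Sx).sum() * (Sy * Sy).sum())
    if denom == 0:
        raise ValueError("RV undefined for a zero-variance matrix")
    return float((Sx * Sy).sum() / denom)


def rv_matrix(omics: list) -> pd.DataFrame:
    """Pairwise RV indices between modalities, on analysis-scale values."""

    names = [m.modality for m in omics]
    mats = [to_analysis_scale(m).T for m in omics]  # samples x features
    out = pd.DataFrame(np.eye(len(omics)), index=names, columns=names)
    for i in range(len(omics)):
        for j in range(i + 1, len(omics)):
            rv = rv_coefficient(mats[i], mats[j])
            out.iloc[i, j] = out.iloc[j, i] = rv
    return out


def spearman_matrix(values: np.ndarray) -> np.ndarray:
    """Feature-by-feature Spearman correlation (features in rows)."""

    ranks = np.apply_along_axis(stats.rankdata, 1, values)
    return np.corrcoef(ranks)


def coexpression_network(matrix: OmicsMatrix, group_mask,
                         edge_threshold: float = 0.3) -> tuple[nx.Graph, float]:
    """Spearman co-expression graph within one sample group.

    Constant features have undefined correlations and are excluded with a
    warning.  Returns (graph with ``weight=rho`` edges where
    |rho| >= threshold, mean absolute off-diagonal rho).
    """

    mask = np.asarray(group_mask, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("need at least 3 samples in the group")
    values = to_analysis_scale(matrix)[:, mask]
    keep = values.std(axis=1) > 0
    if not keep.all():
        dropped = [f for f, k in zip(matrix.feature_ids, keep) if not k]
        warnings.warn(
            f"excluding {len(dropped)} constant features: {dropped[:5]}",
            stacklevel=2,
        )
    fids = [f for f, k in zip(matrix.feature_ids, keep) if k]
    rho = spearman_matrix(values[keep])
    graph = nx.Graph()
    graph.add_nodes_from(fids)
    n = len(fids)
    iu = np.triu_indices(n, k=1)
    mean_abs_rho = float(np.abs(rho[iu]).mean()) if n > 1 else 0.0
    for a, b in zip(*iu):
        r = rho[a, b]
        if abs(r) >= edge_threshold:
            graph.add_edge(fids[a], fids[b], weight=float(r))
    return graph, mean_abs_rho
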