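"""Cluster-quality evaluation: balance, phenotype associations, stability.

The balance index is the normalized entropy of the cluster proportions
(1 for equal sizes, -> 0 as one cluster absorbs everything).  Phenotype
association counting follows the study protocol: per phenotype, a
Wilcoxon rank-sum test for two clusters (Kruskal-Wallis for more),
chi-square for binary/categorical phenotypes, counted at raw P < 0.05
without multiplicity correction.  Stability re-runs a clustering routine
on 80% subsamples and averages pairwise adjusted Rand indices on the
shared samples.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .types import BINARY_PHENOTYPES, PhenotypeTable


def balance_index(labels, k: int | None = None) -> float:
    """Normalized entropy H(cluster proportions) / log(k)."""

    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if k is None:
        k = counts.size
    if k < 2:
        raise ValueError("balance index needs at least 2 clusters")
    p = counts / counts.sum()
    h = -(p * np.log(p)).sum()
    return float(h / np.log(k))


def _is_binary(series: pd.Series) -> bool:
    vals = set(pd.unique(series.dropna()))
    return vals <= {0, 1} or series.name in BINARY_PHENOTYPES


def phenotype_association_count(labels, phenotypes: PhenotypeTable,
                                alpha: float = 0.05, columns=None):
    """Count phenotypes associated with a clustering at raw P < alpha.

    Returns ``(count, table)`` where the table has one row per phenotype
    with its test name and p-value.  Constant phenotypes are skipped with
    a warning.  Rank tests make the count invariant to monotone
    transforms of continuous phenotypes; chi-square handles binary and
    categorical ones (including the group label).
    """

    labels = np.asarray(labels)
    tab = phenotypes.table
    if columns is None:
        columns = [c for c in tab.columns]
    rows = []
    for col in columns:
        series = tab[col]
        if series.nunique() < 2:
            warnings.warn(f"phenotype {col!r} is constant; skipped", stacklevel=2)
            continue
        if series.dtype == object or _is_binary(series):
            ct = pd.crosstab(labels, series)
            if min(ct.shape) < 2:
                warnings.warn(f"degenerate table for {col!r}; skipped",
                              stacklevel=2)
                continue
            chi2, p, _, _ = stats.chi2_contingency(ct.to_numpy(),
                                                   correction=False)
            rows.append((col, "chi2", float(chi2), float(p)))
        else:
            groups = [series.to_numpy()[labels == g] for g in np.unique(labels)]
            if len(groups) == 2:
                res = stats.mannwhitneyu(groups[0], groups[1],
                                         alternative="two-sided")
                rows.append((col, "wilcoxon", float(res.statistic),
                             float(res.pvalue)))
            else:
                res = stats.kruskal(*groups)
                rows.append((col, "kruskal", float(res.statistic),
                             float(res.pvalue)))
    table = pd.DataFrame(rows, columns=["phenotype", "test", "statistic",
                                        "p_value"])
    count = int((table["p_value"] < alpha).sum())
    return count, table


def stability(cluster_fn, sample_ids, n_resamples: int = 10,
              subsample_fraction: float = 0.8, seed: int = 0):
    """Mean pairwise ARI of a clustering routine over sample subsets.

    ``cluster_fn(selected_indices, seed)`` must return integer labels for
    the selected samples.  Each pair of resamples is compared on the
    samples they share.  Returns ``(mean_ari, per_pair_aris)``.
    """

    if n_resamples < 2:
        raise ValueError("need at least 2 resamples")
    n = len(sample_ids)
    m = int(round(subsample_fraction * n))
    if m < 4:
        raise ValueError("subsample too small")
    rng = np.random.default_rng(int(seed))
    runs = []
    for r in range(n_resamples):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        labels = np.asarray(cluster_fn(idx, seed=int(seed) + r + 1))
        runs.append((idx, labels))
    aris = []
    for a in range(len(runs)):
        for b in range(a + 1, len(runs)):
            ia, la = runs[a]
            ib, lb = runs[b]
            shared, pa, pb = np.intersect1d(ia, ib, return_indices=True)
            if shared.size < 4:
                continue
            aris.append(adjusted_rand_score(la[pa], lb[pb]))
    return float(np.mean(aris)), aris


def compare_labelings(labelings: dict, phenotypes: PhenotypeTable,
                      alpha: float = 0.05, phenotype_columns=None):
    """Evaluate several label sets over the same samples side by side.

    ``labelings`` maps a method name to a label vector.  Returns
    ``(report, pairwise_ari)``: one row per labeling with balance and
    association count, plus the pairwise agreement matrix.
    """

    if len(labelings) < 2:
        raise ValueError("need at least two labelings to compare")
    names = list(labelings)
    lengths = {len(np.asarray(v)) for v in labelings.values()}
    if len(lengths) != 1:
        raise ValueError("labelings cover different sample counts; align first")
    rows = []
    for name in names:
        labels = np.asarray(labelings[name])
        k = np.unique(labels).size
        bal = balance_index(labels) if k >= 2 else 0.0
        count, _ = phenotype_association_count(
            labels, phenotypes, alpha=alpha, columns=phenotype_columns
        )
        rows.append((name, k, bal, count))
    report = pd.DataFrame(
        rows, columns=["labeling", "k", "balance", "association_count"]
    )
    ari = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            v = adjusted_rand_score(
                np.asarray(labelings[a]), np.asarray(labelings[b])
            )
            ari.loc[a, b] = ari.loc[b, a] = v
    return report, ari
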