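"""Fracture-risk feature ranking and composite-index screening.

Every candidate feature is scored by the Mann-Whitney AUC of its values
against the binary fracture outcome, in the ALL population (whole
cohort) and the OP population (osteoporosis group only).  Orientation is
chosen per feature so the reported AUC is >= 0.5 (and recorded, since
e.g. low femoral-neck BMD predicts fracture).  Adjusted AUCs residualize
the feature on one of three covariate schemes — (1) age + gender,
(2) + prior fracture, (3) + FN BMD — by least squares inside the
population before re-scoring.  The composite screen exhaustively
enumerates panels of up to four candidate features whose sum-score
(orientation applied, members z-scored within the population by default)
is itself AUC-ranked.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .risk import auc

ADJUSTMENT_SCHEMES = {
    1: ("age", "sex"),
    2: ("age", "sex", "prior_fracture"),
    3: ("age", "sex", "prior_fracture", "fn_bmd"),
}
CANDIDATE_AUC = 0.6  # screening bar for candidate fracture indicators


def oriented_auc(values, labels) -> tuple[float, int]:
    """AUC with orientation so it lands in [0.5, 1]; returns (auc, sign)."""

    a = auc(values, labels)
    return (a, 1) if a >= 0.5 else (1.0 - a, -1)


def _residualize(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(values)), covariates])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariates in adjustment scheme")
    coef, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ coef


def adjusted_auc(values, labels, covariates, orientation: int | None = None):
    """AUC of the covariate-residualized feature.

    If ``orientation`` is given (from the raw ranking) it is applied so
    raw and adjusted AUCs share one direction; otherwise orientation is
    re-chosen on the residuals.
    """

    resid = _residualize(np.asarray(values, dtype=float),
                         np.asarray(covariates, dtype=float))
    if orientation is None:
        a, _ = oriented_auc(resid, labels)
        return a
    return auc(orientation * resid, labels)


def feature_auc_ranking(features: pd.DataFrame, fracture_labels,
                        population_mask=None, covariate_table=None,
                        population: str = "ALL") -> pd.DataFrame:
    """Rank features by fracture-predictive AUC within a population.

    ``features`` holds one column per candidate (omics features on their
    analysis scale, or clinical columns).  With ``covariate_table`` the
    three adjusted AUCs are computed as well.  Output is sorted by raw
    AUC descending; ``candidate`` flags AUC > 0.6.
    """

    y = np.asarray(fracture_labels)
    mask = np.ones(len(y), dtype=bool) if population_mask is None \
        else np.asarray(population_mask, dtype=bool)
    y = y[mask]
    if np.unique(y).size < 2:
        raise ValueError("population has a single fracture class")
    rows = []
    for col in features.columns:
        v = features[col].to_numpy(dtype=float)[mask]
        a, sign = oriented_auc(v, y)
        row = {"feature_id": col, "population": population,
               "orientation": sign, "auc": a, "candidate": a > CANDIDATE_AUC}
        if covariate_table is not None:
            for scheme, cols in ADJUSTMENT_SCHEMES.items():
                cov = covariate_table[list(cols)].to_numpy(dtype=float)[mask]
                row[f"auc_adj{scheme}"] = adjusted_auc(v, y, cov, sign)
        rows.append(row)
    out = pd.DataFrame(rows).sort_values(
        ["auc", "feature_id"], ascending=[False, True], kind="mergesort"
    )
    return out.reset_index(drop=True)


def composite_screen(features: pd.DataFrame, fracture_labels,
                     population_mask=None, max_size: int = 4,
                     orientations=None, zscore: bool = True,
                     covariate_table=None) -> pd.DataFrame:
    """Exhaustive AUC screen of all feature panels of size 1..max_size.

    The panel score is the sum of member values (orientation applied per
    member; members z-scored within the population unless
    ``zscore=False``, which reproduces the literal raw-sum definition).
    Output is deterministic and invariant to candidate input order:
    panels are sorted by AUC descending, then by member names.
    """

    if features.shape[1] == 0:
        raise ValueError("no candidate features")
    if features.shape[1] > 20:
        import warnings

        warnings.warn(
            f"exhaustive screen over {features.shape[1]} candidates is large",
            stacklevel=2,
        )
    y = np.asarray(fracture_labels)
    mask = np.ones(len(y), dtype=bool) if population_mask is None \
        else np.asarray(population_mask, dtype=bool)
    y = y[mask]
    cols = sorted(features.columns)
    vals = {}
    for c in cols:
        v = features[c].to_numpy(dtype=float)[mask]
        if orientations is not None and c in orientations:
            sign = orientations[c]
        else:
            _, sign = oriented_auc(v, y)
        v = sign * v
        if zscore:
            sd = v.std()
            v = (v - v.mean()) / (sd if sd > 0 else 1.0)
        vals[c] = v
    rows = []
    for size in range(1, max_size + 1):
        for panel in combinations(cols, size):
            score = np.sum([vals[c] for c in panel], axis=0)
            a, _ = oriented_auc(score, y)
            row = {"members": "+".join(panel), "size": size, "auc": a}
            if covariate_table is not None:
                cov = covariate_table[
                    list(ADJUSTMENT_SCHEMES[3])
                ].to_numpy(dtype=float)[mask]
                row["auc_adj3"] = adjusted_auc(score, y, cov)
            rows.append(row)
    out = pd.DataFrame(rows).sort_values(
        ["auc", "members"], ascending=[False, True], kind="mergesort"
    )
    return out.reset_index(drop=True)
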