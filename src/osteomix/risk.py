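"""Logistic-regression risk models with mRMR selection and AUC evaluation.

Three nested tiers mirror the study design: Baseline I uses conventional
risk factors (age, BMI, drinking and smoking history), Baseline II adds
the bone turnover markers (beta-CTX, OST, PINP), and the full model adds
the selected multi-modal molecular signatures (M3S).  Feature selection
is greedy mRMR with the mutual-information-difference (MID) criterion on
4-bin equal-frequency discretized features, run on the training split
only.  Evaluation is a seed-fixed stratified 70/30 split with
Mann-Whitney AUC (DeLong confidence intervals) and decision-curve net
benefit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

BASELINE1_FEATURES = ("age", "bmi", "drinking", "smoking")
BTM_FEATURES = ("beta_ctx", "ost", "pinp")


@dataclass
class RiskModelSpec:
    tier: str = "m3s"  # baseline1 | baseline2 | m3s
    m3s_features: tuple = ()
    include_gender: bool = False
    n_select: int = 5
    split_fraction: float = 0.7
    seed: int = 0

    def feature_names(self) -> list[str]:
        feats = list(BASELINE1_FEATURES)
        if self.include_gender:
            feats.append("sex")
        if self.tier in ("baseline2", "m3s"):
            feats += list(BTM_FEATURES)
        if self.tier == "m3s":
            feats += list(self.m3s_features)
        if self.tier not in ("baseline1", "baseline2", "m3s"):
            raise ValueError(f"unknown tier {self.tier!r}")
        return feats


# ---------------------------------------------------------------------------
# mRMR


def _discretize(col: np.ndarray, bins: int = 4) -> np.ndarray:
    """Equal-frequency binning (ties collapse bins; constants -> one bin)."""

    qs = np.quantile(col, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(np.unique(qs), col, side="right")


def _mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """MI in nats from the joint contingency table of two discrete vectors."""

    table = pd.crosstab(x, y).to_numpy(dtype=float)
    pxy = table / table.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float((pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])).sum())


def mrmr_select(features: pd.DataFrame, labels, n_select: int,
                bins: int = 4) -> list[str]:
    """Greedy mRMR with the MID criterion.

    First pick maximizes relevance MI(f; label); each later pick
    maximizes MI(f; label) - mean MI(f; already selected).  Continuous
    features are discretized into equal-frequency bins; ties break
    lexicographically on the feature name, so selection is deterministic.
    """

    if n_select > features.shape[1]:
        raise ValueError("n_select exceeds the number of features")
    y = np.asarray(labels)
    cols = sorted(features.columns)
    disc = {c: _discretize(features[c].to_numpy(dtype=float), bins)
            for c in cols}
    relevance = {c: _mutual_information(disc[c], y) for c in cols}
    selected: list[str] = []
    remaining = list(cols)
    pair_mi: dict = {}
    while len(selected) < n_select:
        best, best_score = None, -np.inf
        for c in remaining:
            if selected:
                red = np.mean([
                    pair_mi.setdefault(
                        (c, s), _mutual_information(disc[c], disc[s])
                    )
                    for s in selected
                ])
            else:
                red = 0.0
            score = relevance[c] - red
            if score > best_score + 1e-12:
                best, best_score = c, score
        selected.append(best)
        remaining.remove(best)
    return selected


# ---------------------------------------------------------------------------
# logistic model


@dataclass
class FittedRiskModel:
    spec: RiskModelSpec
    features: list
    coef: pd.Series          # on the original feature scale
    coef_se: pd.Series       # Wald standard errors, original scale
    intercept: float
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    model: LogisticRegression = field(repr=False, default=None)

    def predict_proba(self, data: pd.DataFrame) -> np.ndarray:
        X = data[self.features].to_numpy(dtype=float)
        Xs = (X - self.scaler_mean) / self.scaler_std
        return self.model.predict_proba(Xs)[:, 1]


def fit_logistic(features: pd.DataFrame, outcome, spec: RiskModelSpec,
                 ridge_eps: float = 1e-6) -> FittedRiskModel:
    """Maximum-likelihood logistic fit with a small L2 ridge for stability.

    Inputs are standardized internally; reported coefficients are mapped
    back to the original feature scale.  Perfect separation converges to
    a finite ridge fit (a warning is left to the caller's diagnostics).
    """

    y = np.asarray(outcome)
    if np.unique(y).size != 2:
        raise ValueError("outcome must contain both classes")
    names = list(features.columns)
    X = features.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std == 0, 1.0, std)
    Xs = (X - mean) / std
    model = LogisticRegression(
        C=1.0 / ridge_eps, solver="lbfgs", max_iter=5000
    )
    model.fit(Xs, y)
    coef_std = model.coef_[0]
    coef = coef_std / std
    intercept = float(model.intercept_[0] - (coef_std * mean / std).sum())
    # Wald SEs from the observed Fisher information on the fitted model
    prob = model.predict_proba(Xs)[:, 1]
    w = prob * (1.0 - prob)
    design = np.column_stack([np.ones(len(y)), Xs])
    info = design.T @ (design * w[:, None])
    cov = np.linalg.pinv(info)
    se_std = np.sqrt(np.diag(cov)[1:])
    return FittedRiskModel(
        spec=spec, features=names,
        coef=pd.Series(coef, index=names),
        coef_se=pd.Series(se_std / std, index=names),
        intercept=intercept,
        scaler_mean=mean, scaler_std=std, model=model,
    )


# ---------------------------------------------------------------------------
# AUC, DeLong, decision curves


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: U / (n1 * n0), ties counted one half."""

    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def delong_ci(scores, labels, alpha: float = 0.05):
    """DeLong variance and normal-approximation CI for a single AUC."""

    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos, neg = s[y == 1], s[y == 0]
    m, n = pos.size, neg.size
    theta = auc(s, y)
    # placement values
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
        (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    se = np.sqrt(var)
    zq = stats.norm.ppf(1 - alpha / 2)
    return theta, max(0.0, theta - zq * se), min(1.0, theta + zq * se)


def roc_points(scores, labels) -> pd.DataFrame:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    tps = np.concatenate([[0], np.cumsum(y_sorted == 1)])
    fps = np.concatenate([[0], np.cumsum(y_sorted == 0)])
    return pd.DataFrame({
        "fpr": fps / max(fps[-1], 1), "tpr": tps / max(tps[-1], 1),
    })


def decision_curve(scores, labels, thresholds) -> pd.DataFrame:
    """Net benefit NB(pt) = TP/n - (FP/n) * pt/(1-pt) at rule score >= pt,
    alongside treat-all and treat-none reference strategies."""

    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n = y.size
    prevalence = y.mean()
    rows = []
    for pt in thresholds:
        if not 0.0 < pt < 1.0:
            raise ValueError("thresholds must lie strictly inside (0,1)")
        flag = s >= pt
        tp = np.sum(flag & (y == 1)) / n
        fp = np.sum(flag & (y == 0)) / n
        odds = pt / (1.0 - pt)
        nb = tp - fp * odds
        nb_all = prevalence - (1.0 - prevalence) * odds
        rows.append((pt, nb, nb_all, 0.0))
    return pd.DataFrame(rows, columns=["threshold", "net_benefit",
                                       "treat_all", "treat_none"])


# ---------------------------------------------------------------------------
# end-to-end train/eval


@dataclass
class ModelEvaluation:
    tier: str
    selected_features: list
    coef: pd.Series
    train_auc: float
    test_auc: float
    test_auc_ci: tuple
    roc: pd.DataFrame
    decision: pd.DataFrame
    train_index: np.ndarray
    test_index: np.ndarray


def train_eval(data: pd.DataFrame, outcome_col: str,
               spec: RiskModelSpec,
               thresholds=np.linspace(0.05, 0.6, 12)) -> ModelEvaluation:
    """Stratified 70/30 split, training-only mRMR, held-out metrics.

    ``data`` holds one row per sample with the outcome column and every
    candidate feature.  For the m3s tier, mRMR reduces the declared M3S
    features to ``spec.n_select`` on the training split only; baseline
    covariates always enter the model.
    """

    y = data[outcome_col].to_numpy()
    idx = np.arange(len(data))
    train_idx, test_idx = train_test_split(
        idx, train_size=spec.split_fraction, stratify=y,
        random_state=int(spec.seed),
    )
    feats = spec.feature_names()
    base = [f for f in feats if f not in spec.m3s_features]
    if spec.tier == "m3s" and spec.m3s_features:
        n_sel = min(spec.n_select, len(spec.m3s_features))
        chosen = mrmr_select(
            data.iloc[train_idx][list(spec.m3s_features)], y[train_idx], n_sel
        )
        feats = base + chosen
    model = fit_logistic(data.iloc[train_idx][feats], y[train_idx], spec)
    train_scores = model.predict_proba(data.iloc[train_idx])
    test_scores = model.predict_proba(data.iloc[test_idx])
    test_auc, lo, hi = delong_ci(test_scores, y[test_idx])
    return ModelEvaluation(
        tier=spec.tier,
        selected_features=feats,
        coef=model.coef,
        train_auc=auc(train_scores, y[train_idx]),
        test_auc=test_auc,
        test_auc_ci=(lo, hi),
        roc=roc_points(test_scores, y[test_idx]),
        decision=decision_curve(test_scores, y[test_idx], thresholds),
        train_index=train_idx,
        test_index=test_idx,
    )
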