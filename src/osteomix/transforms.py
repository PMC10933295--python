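"""Modality-specific value transforms.

Methylation beta values are analysed on the logit (M-value-like) scale,
metabolite abundances on the log scale, and microbiota relative abundances
after a centered log-ratio (CLR) transform with a half-minimum pseudocount.
These transforms put every modality on an approximately Gaussian scale
before correlation, standardization, encoding, or linear-model fitting.
"""

from __future__ import annotations

import numpy as np

from .types import OmicsMatrix


def logit(p: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    p = np.clip(p, eps, 1.0 - eps)
    return np.log(p / (1.0 - p))


def inv_logit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def clr(values: np.ndarray, pseudocount: float | None = None) -> np.ndarray:
    """Centered log-ratio over features, column-wise (samples in columns).

    ``pseudocount`` defaults to half the smallest positive entry of the
    matrix, added everywhere so zero abundances stay finite.
    """

    v = np.asarray(values, dtype=float)
    if pseudocount is None:
        positive = v[v > 0]
        if positive.size == 0:
            raise ValueError("CLR undefined for an all-zero matrix")
        pseudocount = 0.5 * positive.min()
    logv = np.log(v + pseudocount)
    return logv - logv.mean(axis=0, keepdims=True)


def to_analysis_scale(matrix: OmicsMatrix) -> np.ndarray:
    """Transform an omics matrix to its modality's analysis scale."""

    if matrix.value_semantics == "beta01":
        return logit(matrix.values)
    if matrix.value_semantics == "positive_abundance":
        return np.log(matrix.values + 1e-12)
    if matrix.value_semantics == "relative_abundance":
        return clr(matrix.values)
    raise ValueError(f"unknown semantics {matrix.value_semantics!r}")


def standardize(values: np.ndarray, axis: int = 1) -> np.ndarray:
    """Z-score along ``axis``; zero-variance rows/columns become zeros."""

    mean = values.mean(axis=axis, keepdims=True)
    std = values.std(axis=axis, keepdims=True)
    std = np.where(std == 0, 1.0, std)
    return (values - mean) / std
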