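"""SNP quality control: call rate, minor allele frequency, and the
Hardy-Weinberg exact test.

A variant is kept only if call rate >= 95%, MAF >= 5% and the exact HWE
p-value >= 1e-5; each exclusion is reported with its reason.  MAF is
computed on non-missing calls only.  The HWE test is the exact conditional
test (two-sided, "probability at most that of the observed configuration"
rule) rather than the chi-square approximation, which is unreliable at low
minor-allele counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .types import GenotypeMatrix


@dataclass
class SnpQcThresholds:
    min_call_rate: float = 0.95
    min_maf: float = 0.05
    hwe_p_floor: float = 1e-5

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "hwe_p_floor"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1)")


def _log_het_prob(n_het: np.ndarray, n: int, n_rare: int) -> np.ndarray:
    """log P(#het = n_het | n genotypes, n_rare rare alleles) under HWE."""

    n_rr = (n_rare - n_het) // 2
    n_cc = n - n_het - n_rr
    return (
        n_het * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(n_het + 1)
        - gammaln(n_rr + 1)
        - gammaln(n_cc + 1)
        - (gammaln(2 * n + 1) - gammaln(n_rare + 1) - gammaln(2 * n - n_rare + 1))
    )


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test.

    Conditions on the allele counts and sums the probabilities of all
    heterozygote configurations whose probability does not exceed that of
    the observed configuration.
    """

    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be nonnegative")
    n = sum(counts)
    if n < 1:
        raise ValueError("at least one genotype required")
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_rare == 0:
        return 1.0
    # heterozygote counts share the parity of the rare-allele count
    h_min = n_rare % 2
    h = np.arange(h_min, min(n_rare, 2 * n - n_rare) + 1, 2)
    logp = _log_het_prob(h, n, n_rare)
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[(h == n_het).argmax()]
    if n_het not in h:  # impossible configuration given allele counts
        raise ValueError("inconsistent genotype counts")
    p = probs[probs <= obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def filter_snps(genotypes: GenotypeMatrix,
                thresholds: SnpQcThresholds | None = None):
    """Apply the QC thresholds; returns (filtered matrix, report).

    The report has one row per variant with its metrics, whether it was
    kept, and the (first) reason for exclusion.  Filtering an already
    filtered matrix changes nothing.
    """

    if genotypes.n_variants < 1:
        raise ValueError("genotype matrix has no variants")
    thresholds = thresholds or SnpQcThresholds()
    call_rate = genotypes.call_rate()
    maf = genotypes.maf()
    hwe_p = np.ones(genotypes.n_variants)
    for j in range(genotypes.n_variants):
        d = genotypes.dosages[:, j]
        d = d[~np.isnan(d)]
        if d.size == 0:
            hwe_p[j] = 1.0
            continue
        hwe_p[j] = hwe_exact_test(
            int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())
        )
    reasons = np.full(genotypes.n_variants, "", dtype=object)
    reasons[hwe_p < thresholds.hwe_p_floor] = "hwe"
    reasons[maf < thresholds.min_maf] = "maf"
    reasons[call_rate < thresholds.min_call_rate] = "call_rate"
    kept = reasons == ""
    report = pd.DataFrame(
        {
            "variant_id": genotypes.variants["id"].to_numpy(),
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe_p,
            "kept": kept,
            "reason": reasons,
        }
    )
    if not kept.any():
        import warnings

        warnings.warn("all variants removed by QC", stacklevel=2)
    return genotypes.subset_variants(kept), report
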