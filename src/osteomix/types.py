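"""Shared data model for the multi-omics osteoporosis pipeline.

All omics matrices are oriented features x samples.  Genotype dosages are
samples x variants with NaN marking missing calls.  Every container carries
an explicit ordered list of sample IDs so that :func:`align_samples` can
restrict a heterogeneous collection of objects to their common cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

MODALITIES = ("methylation", "metabolite", "microbiota")

#: value semantics implied by each modality
MODALITY_SEMANTICS = {
    "methylation": "beta01",
    "metabolite": "positive_abundance",
    "microbiota": "relative_abundance",
}

_REL_TOL = 1e-6


class ValidationError(ValueError):
    """Raised when a container violates its declared invariants."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicated {what} ID: {i!r}")
        seen.add(i)
    return ids


@dataclass
class OmicsMatrix:
    """One modality's feature-by-sample numeric matrix."""

    modality: str
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # (n_features, n_samples)
    value_semantics: str = ""

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        if not self.value_semantics:
            self.value_semantics = MODALITY_SEMANTICS[self.modality]
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} inconsistent with "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if np.isnan(self.values).any():
            bad = self.feature_ids[int(np.where(np.isnan(self.values))[0][0])]
            raise ValidationError(f"missing value in feature {bad!r}")
        self.validate_semantics()

    def validate_semantics(self) -> None:
        if self.value_semantics == "beta01":
            bad = (self.values < 0) | (self.values > 1)
            if bad.any():
                fid = self.feature_ids[int(np.where(bad.any(axis=1))[0][0])]
                raise ValidationError(
                    f"beta value outside [0,1] in feature {fid!r}"
                )
        elif self.value_semantics == "positive_abundance":
            if (self.values < 0).any():
                bad = (self.values < 0)
                fid = self.feature_ids[int(np.where(bad.any(axis=1))[0][0])]
                raise ValidationError(f"negative abundance in feature {fid!r}")
        elif self.value_semantics == "relative_abundance":
            sums = self.values.sum(axis=0)
            off = np.abs(sums - 1.0) > _REL_TOL
            if off.any():
                sid = self.sample_ids[int(np.where(off)[0][0])]
                raise ValidationError(
                    f"relative abundances of sample {sid!r} sum to "
                    f"{sums[off][0]:.8f}, not 1"
                )
        else:
            raise ValidationError(
                f"unknown value semantics {self.value_semantics!r}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OmicsMatrix(
            self.modality,
            list(self.feature_ids),
            list(sample_ids),
            self.values[:, idx],
            self.value_semantics,
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "OmicsMatrix":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return OmicsMatrix(
            self.modality,
            list(feature_ids),
            list(self.sample_ids),
            self.values[idx, :],
            self.value_semantics,
        )


@dataclass
class GenotypeMatrix:
    """Sample-by-variant additive dosages with variant metadata.

    ``variants`` columns: id, chrom, pos (1-based), ref, alt.
    ``dosages`` entries are 0/1/2 or NaN for missing calls.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray  # (n_samples, n_variants)

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        required = {"id", "chrom", "pos", "ref", "alt"}
        missing = required - set(self.variants.columns)
        if missing:
            raise ValidationError(f"variant table lacks columns {sorted(missing)}")
        self.variants = self.variants.reset_index(drop=True)
        if (self.variants["pos"] < 1).any():
            raise ValidationError("variant pos must be >= 1 (1-based)")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        obs = self.dosages[~np.isnan(self.dosages)]
        if not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValidationError("dosage entries must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant, on non-missing calls only."""
        with np.errstate(invalid="ignore"):
            p_alt = np.nanmean(self.dosages, axis=0) / 2.0
        p_alt = np.where(np.isnan(p_alt), 0.0, p_alt)
        return np.minimum(p_alt, 1.0 - p_alt)

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return GenotypeMatrix(
            list(sample_ids), self.variants.copy(), self.dosages[idx, :]
        )

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            list(self.sample_ids),
            self.variants.loc[mask].reset_index(drop=True),
            self.dosages[:, mask],
        )


GROUPS = ("normal", "osteopenia", "osteoporosis")

CONTINUOUS_PHENOTYPES = (
    "age", "bmi", "th_bmd", "fn_bmd", "l1l4_bmd", "l1l4_bmdz",
    "beta_ctx", "ost", "pinp", "alp", "followup_bmd_delta",
)
BINARY_PHENOTYPES = (
    "sex", "prior_fracture", "fracture", "smoking", "drinking",
)


@dataclass
class PhenotypeTable:
    """Per-sample clinical table with typed columns.

    Continuous columns are floats, binary columns are 0/1 integers, and
    ``group`` is one of normal/osteopenia/osteoporosis.
    """

    table: pd.DataFrame  # indexed by sample id

    def __post_init__(self) -> None:
        if "group" not in self.table.columns:
            raise ValidationError("phenotype table lacks a 'group' column")
        _check_unique(self.table.index, "sample")
        bad = ~self.table["group"].isin(GROUPS)
        if bad.any():
            raise ValidationError(
                f"unknown group label {self.table['group'][bad].iloc[0]!r}"
            )
        tab = self.table.copy()
        for col in tab.columns:
            if col == "group":
                continue
            if col in BINARY_PHENOTYPES or set(tab[col].dropna().unique()) <= {0, 1}:
                vals = tab[col]
                if not vals.isin((0, 1)).all():
                    raise ValidationError(f"binary column {col!r} has non-0/1 values")
                tab[col] = vals.astype(int)
            else:
                tab[col] = pd.to_numeric(tab[col], errors="raise").astype(float)
        tab.index = tab.index.astype(str)
        self.table = tab

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def subset_samples(self, sample_ids: Sequence[str]) -> "PhenotypeTable":
        return PhenotypeTable(self.table.loc[list(sample_ids)].copy())

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]


@dataclass
class GeneIntervalSet:
    """Gene intervals in half-open 0-based (BED) coordinates.

    ``records`` columns: chrom, start, end, gene_id and optional
    feature_class in {gene, exon, intron}.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"chrom", "start", "end", "gene_id"}
        missing = req - set(self.records.columns)
        if missing:
            raise ValidationError(f"interval table lacks columns {sorted(missing)}")
        rec = self.records.copy()
        if "feature_class" not in rec.columns:
            rec["feature_class"] = "gene"
        if (rec["start"] >= rec["end"]).any():
            raise ValidationError("intervals must satisfy start < end")
        rec = rec.sort_values(["chrom", "start", "end"], kind="mergesort")
        self.records = rec.reset_index(drop=True)

    @property
    def chroms(self) -> set[str]:
        return set(self.records["chrom"].astype(str))


def align_samples(*objects):
    """Restrict objects carrying sample IDs to their shared samples.

    The intersection is ordered by the first argument.  Returns
    ``(aligned_objects, dropped)`` where ``dropped`` maps the argument index
    to the list of sample IDs removed from that object.
    """

    if len(objects) < 2:
        raise ValueError("align_samples needs at least two objects")
    id_lists = [list(o.sample_ids) for o in objects]
    shared = set(id_lists[0])
    for ids in id_lists[1:]:
        shared &= set(ids)
    if not shared:
        raise ValueError("no shared samples across objects")
    order = [s for s in id_lists[0] if s in shared]
    dropped = {
        i: [s for s in ids if s not in shared] for i, ids in enumerate(id_lists)
    }
    aligned = tuple(o.subset_samples(order) for o in objects)
    return aligned, dropped
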