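"""Readers and writers for every on-disk artifact.

Conventions, fixed and tested:

* omics matrices: TSV, feature rows x sample columns, first column holds
  feature IDs under the header ``feature_id``;
* genotypes: minimal VCF v4.2 carrying only the GT FORMAT field (read via
  cyvcf2) or an equivalent dosage TSV (variants x samples);
* phenotypes: CSV with ``sample_id`` as the first column;
* gene intervals: BED, 0-based half-open, 4th column = gene ID, optional
  5th column = feature class (exon/intron);
* floats are serialized at 10 significant digits so that write -> read ->
  write round trips are byte-identical.

VCF POS is 1-based; BED coordinates are 0-based half-open.  The conversion
(``pos - 1`` lands inside ``[start, end)``) is handled in
:mod:`osteomix.xqtl` and covered by boundary tests.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    GeneIntervalSet,
    GenotypeMatrix,
    OmicsMatrix,
    PhenotypeTable,
    ValidationError,
)

FLOAT_FMT = "%.10g"


def _format_float(x: float) -> str:
    return FLOAT_FMT % x


# ---------------------------------------------------------------------------
# omics matrices


def read_omics(path, modality: str, value_semantics: str = "",
               impute: str | None = None) -> OmicsMatrix:
    """Load a feature-by-sample TSV as a validated :class:`OmicsMatrix`.

    ``impute="median"`` fills missing cells with the per-feature median;
    by default any missing cell is an error (downstream math assumes
    complete matrices).
    """

    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    if np.isnan(values).any():
        if impute == "median":
            med = np.nanmedian(values, axis=1, keepdims=True)
            values = np.where(np.isnan(values), med, values)
        else:
            raise ValidationError(
                f"missing values in {path}; pass impute='median' to fill them"
            )
    return OmicsMatrix(
        modality=modality,
        feature_ids=list(df.index.astype(str)),
        sample_ids=list(df.columns.astype(str)),
        values=values,
        value_semantics=value_semantics,
    )


def write_omics(matrix: OmicsMatrix, path) -> None:
    df = matrix.to_frame()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path) -> GenotypeMatrix:
    """Read genotypes from a minimal VCF (``.vcf``) or a dosage TSV."""

    path = Path(path)
    if path.suffix == ".vcf" or path.name.endswith(".vcf.gz"):
        return _read_vcf(path)
    return _read_dosage_tsv(path)


def _read_vcf(path: Path) -> GenotypeMatrix:
    import cyvcf2

    vcf = cyvcf2.VCF(str(path))
    sample_ids = list(vcf.samples)
    ids, chroms, poss, refs, alts = [], [], [], [], []
    rows = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValidationError(
                f"multi-allelic record {rec.ID or rec.POS} not supported"
            )
        ids.append(rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        dose = np.empty(len(sample_ids))
        for i, gt in enumerate(rec.genotypes):
            a, b = gt[0], gt[1]
            dose[i] = np.nan if (a < 0 or b < 0) else float(a + b)
        rows.append(dose)
    vcf.close()
    variants = pd.DataFrame(
        {"id": ids, "chrom": chroms, "pos": poss, "ref": refs, "alt": alts}
    )
    dosages = (
        np.asarray(rows).T if rows else np.empty((len(sample_ids), 0))
    )
    return GenotypeMatrix(sample_ids, variants, dosages)


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 with GT as the only FORMAT field."""

    buf = _io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    for chrom in pd.unique(genotypes.variants["chrom"]):
        buf.write(f"##contig=<ID={chrom}>\n")
    buf.write(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    )
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(genotypes.sample_ids)
        + "\n"
    )
    gt_strings = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for j, var in genotypes.variants.iterrows():
        calls = [
            "./." if np.isnan(d) else gt_strings[d]
            for d in genotypes.dosages[:, j]
        ]
        buf.write(
            f"{var['chrom']}\t{int(var['pos'])}\t{var['id']}\t{var['ref']}\t"
            f"{var['alt']}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
        )
    Path(path).write_text(buf.getvalue())


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["id", "chrom", "pos", "ref", "alt"]
    missing = set(meta_cols) - set(df.columns)
    if missing:
        raise ValidationError(f"dosage TSV lacks columns {sorted(missing)}")
    sample_ids = [c for c in df.columns if c not in meta_cols]
    dosages = df[sample_ids].to_numpy(dtype=float).T
    return GenotypeMatrix(sample_ids, df[meta_cols].copy(), dosages)


def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    df = genotypes.variants[["id", "chrom", "pos", "ref", "alt"]].copy()
    dose = genotypes.dosages
    for i, sid in enumerate(genotypes.sample_ids):
        col = dose[i, :]
        df[sid] = [("" if np.isnan(d) else "%d" % int(d)) for d in col]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phenotypes


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, index_col="sample_id")
    return PhenotypeTable(df)


def write_phenotypes(phenotypes: PhenotypeTable, path) -> None:
    df = phenotypes.table.copy()
    df.index.name = "sample_id"
    df.to_csv(path, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# gene intervals (BED)


def read_bed(path) -> GeneIntervalSet:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValidationError(
                    f"{path}:{ln}: BED needs >= 4 columns (chrom start end gene)"
                )
            chrom, start, end, gene = parts[:4]
            feature_class = parts[4] if len(parts) > 4 else "gene"
            rows.append((chrom, int(start), int(end), gene, feature_class))
    return GeneIntervalSet(
        pd.DataFrame(
            rows, columns=["chrom", "start", "end", "gene_id", "feature_class"]
        )
    )


def write_bed(intervals: GeneIntervalSet, path) -> None:
    intervals.records[
        ["chrom", "start", "end", "gene_id", "feature_class"]
    ].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# configuration


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
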