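"""osteomix: multi-omics osteoporosis subtyping and fracture-risk analysis.

An end-to-end pipeline for integrating methylation, metabolite and
microbiota profiles with genotypes and clinical phenotypes: deep latent
space fusion (DLSF) clustering into clinical subtypes, differential
association matrix (DAM) characterization, xQTL genotype scans,
tiered logistic risk models, and AUC-ranked composite fracture-risk
indices — plus a synthetic cohort generator that emulates the study's
statistical structure for testing and benchmarking.
"""

from importlib import resources

import pandas as pd

__version__ = "0.1.0"

__all__ = ["load_panel", "__version__"]

PANELS = (
    "op_identification_m3s",
    "subtype_recognition_m3s",
    "fracture_composite_cpgs",
)


def load_panel(name: str) -> pd.DataFrame:
    """Load one of the published reference signature panels shipped with
    the package (modality, feature_id)."""

    if name not in PANELS:
        raise ValueError(f"unknown panel {name!r}; available: {PANELS}")
    with resources.files("osteomix.panels").joinpath(f"{name}.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
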