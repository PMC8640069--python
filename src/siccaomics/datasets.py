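"""Bundled reference tables.

``mediation_catalog`` is a transcription of reported whole-blood
Sjögren's-syndrome meQTL/eQTL mediation candidates: per SNP-feature pair,
the per-allele molecular effect (``beta_qtl``), the case-control effect of
the molecular feature (``beta_disease``: beta-scale methylation difference
or log2 fold change) and the allelic disease odds ratio with its p-value.
It is used to exercise the mediation-direction classifier against published
sign patterns.
"""

from importlib import resources

import pandas as pd

__all__ = ["mediation_catalog"]


def mediation_catalog() -> pd.DataFrame:
    with resources.files("siccaomics.data").joinpath("mediation_catalog.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
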