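"""Bundled reference tables from a published three-cohort RRBS comparison.

The tables describe differentially methylated fragments shared by two
post-viral disease contrasts — Long COVID vs healthy controls (contrast A)
and ME/CFS vs healthy controls (contrast B) — in PBMC DNA:

* :func:`load_divergent_dmf_table` — the 26 shared DMFs whose methylation
  change differs by more than 10 percentage points between the two disease
  cohorts, with genomic location labels, associated gene ids (gene-feature
  rows only) and the per-contrast differences in percentage points;
* :func:`load_promoter_exon_dmf_table` — the shared DMFs sitting in gene
  promoters (12) and exons (6), with the same difference columns;
* :func:`load_cohort_sample_sheet` — the age/sex-matched cohort design
  (three groups of five), used as the default layout for simulations.

All printed differences are rounded to 0.1 pp, so the reported cross-cohort
column can deviate from ``delta_a - delta_b`` by up to 0.2 pp.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .coverage import SampleSheet

__all__ = [
    "load_divergent_dmf_table",
    "load_promoter_exon_dmf_table",
    "load_cohort_sample_sheet",
]


def _data_path(name: str):
    return resources.files("dmfkit.data").joinpath(name)


def load_divergent_dmf_table() -> pd.DataFrame:
    """26 shared DMFs diverging by >10 pp between the two disease cohorts.

    Columns: ``chrom``, ``start``, ``end``, ``location``, ``gene_id``
    (empty for intergenic rows), ``delta_a`` (Long COVID vs HC, pp),
    ``delta_b`` (ME/CFS vs HC, pp) and ``delta_ab`` (the reported
    cross-cohort difference), sorted ascending by ``delta_ab``.
    """
    with resources.as_file(_data_path("divergent_dmfs.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"chrom": str})


def load_promoter_exon_dmf_table() -> pd.DataFrame:
    """Shared DMFs in gene promoters and exons (``region`` column)."""
    with resources.as_file(_data_path("promoter_exon_dmfs.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"chrom": str})


def load_cohort_sample_sheet() -> SampleSheet:
    """The matched HC/ME/LC cohort design: five samples per group."""
    with resources.as_file(_data_path("cohort_samples.csv")) as p:
        return SampleSheet.from_csv(p)
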