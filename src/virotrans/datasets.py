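"""Packaged reference tables from the published study.

These are the study's printed summary tables, shipped as small TSVs:
the seven-culture phenotype panel (CD50 cytotoxic dose, apoptotic
fractions, proliferation index), the universal infection-response gene
lists at 12 h and 24 h, and the top-25 commonly expressed viral
transcripts with their published average ranks.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .datatypes import validate_phenotype_table


def _data_path(name: str):
    return resources.files("virotrans.data").joinpath(name)


def load_culture_phenotypes() -> pd.DataFrame:
    """Seven glioma/normal-brain cultures with CD50 (PFU/cell), apoptotic
    fractions (AnnV+/PI- and AnnV+/PI+, %) and cell index."""
    with resources.as_file(_data_path("culture_phenotypes.tsv")) as p:
        return validate_phenotype_table(pd.read_csv(p, sep="\t"))


def load_universal_response_genes() -> pd.DataFrame:
    """Genes up-/down-regulated in every culture, per timepoint.

    Columns: timepoint_h, direction ('up'/'down'), gene_id.
    """
    with resources.as_file(_data_path("universal_response_genes.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def universal_gene_lists(timepoint_h: int) -> tuple[list[str], list[str]]:
    """(up, down) universal gene id lists for the given timepoint."""
    df = load_universal_response_genes()
    df = df[df["timepoint_h"] == timepoint_h]
    up = df.loc[df["direction"] == "up", "gene_id"].tolist()
    down = df.loc[df["direction"] == "down", "gene_id"].tolist()
    return up, down


def load_viral_top_transcripts() -> pd.DataFrame:
    """Top-25 commonly expressed viral transcripts (published average ranks)."""
    with resources.as_file(_data_path("viral_top_transcripts.tsv")) as p:
        return pd.read_csv(p, sep="\t")
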