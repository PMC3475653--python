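"""Packaged reference tables and loaders.

Two fixtures ship with the package, transcribed verbatim from the
published study of the fission-yeast G2-M mutants:

* ``g2m_cell_lengths`` — in-vivo cell lengths at septation for the eight
  mutant strains and wild type, measured over 30 septated cells at the
  permissive (25C) and semi-restrictive (30C) temperatures.
* ``g2m_mutations`` — the eight missense mutations in Cdk1/CycB with
  their per-state ddG values (kcal/mol), impact class, the published
  control coefficients and the published SIF scores.

The MAPK protein-to-channel mapping is a *synthetic stand-in* (the
study's own assignment table lives in supplementary material that is not
redistributed here); it is an editable TSV with one row per
(protein, impact class) pair.
"""

from __future__ import annotations

import importlib.resources as resources
import pathlib

import pandas as pd

from .ddg import read_mutations

__all__ = ["data_path", "load_cell_lengths", "load_g2m_mutation_table",
           "load_g2m_mutations", "load_mapk_mapping", "MAPK_MAPPING_FILE"]

MAPK_MAPPING_FILE = "mapk_channel_mapping.synthetic.tsv"


def data_path(name: str) -> pathlib.Path:
    """Filesystem path of a packaged data file."""
    return pathlib.Path(resources.files("sifkit").joinpath("data", name))


def load_cell_lengths() -> pd.DataFrame:
    """Cell-length phenotype table (one row per strain, incl. wild type)."""
    return pd.read_csv(data_path("g2m_cell_lengths.tsv"), sep="\t",
                       dtype={"strain_number": str, "strain_name": str})


def load_g2m_mutation_table() -> pd.DataFrame:
    """Raw G2-M mutation fixture including published C and SIF columns."""
    df = pd.read_csv(data_path("g2m_mutations.tsv"), sep="\t")
    return df


def load_g2m_mutations():
    """G2-M mutation fixture as :class:`~sifkit.ddg.MutationRecord` rows."""
    return read_mutations(data_path("g2m_mutations.tsv"))


def load_mapk_mapping(path=None) -> pd.DataFrame:
    """Protein/class -> channel mapping for MAPK mutations.

    Defaults to the packaged synthetic stand-in table; pass a path to use
    a custom mapping with the same columns
    (protein, impact_class, channels, weights — comma-separated lists).
    """
    src = data_path(MAPK_MAPPING_FILE) if path is None else path
    return pd.read_csv(src, sep="\t", dtype=str)
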