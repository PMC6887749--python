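"""Packaged reference tables.

* ``table1_motifs.tsv`` — the 20 conserved protein motifs of the family
  survey, transcribed with their consensus strings (extended alphabet),
  printed E-values (opaque text) and site counts.
* ``cis_elements.tsv`` — a starter promoter cis-element dictionary
  (W-box, ABRE and other common stress/phytohormone elements).  It is
  illustrative: users studying real promoters should supply their own
  dictionary.
* ``rosaceae_member_counts.csv`` — the published per-species family-member
  counts for the nine surveyed Rosaceae genomes.
"""

from __future__ import annotations

from importlib import resources as _ir

import pandas as pd

from .io import (CisElementDefinition, MotifDefinition, read_element_table,
                 read_motif_table)


def _data_path(name: str):
    return _ir.files("famsurvey").joinpath("data", name)


def default_motifs() -> list[MotifDefinition]:
    with _ir.as_file(_data_path("table1_motifs.tsv")) as path:
        return read_motif_table(path)


def default_cis_elements() -> list[CisElementDefinition]:
    with _ir.as_file(_data_path("cis_elements.tsv")) as path:
        return read_element_table(path)


def rosaceae_member_counts() -> pd.Series:
    """Published per-species member counts, indexed by species name."""
    with _ir.as_file(_data_path("rosaceae_member_counts.csv")) as path:
        df = pd.read_csv(path)
    return df.set_index("species")["members"]
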