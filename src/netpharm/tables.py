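"""Packaged reference tables of the dragon's-blood tablet study.

Two small TSVs ship with the package: the UPLC-ESI-MS compound table
(one row per measured quasi-molecular ion, with formula, expected m/z,
Papp and a previously-reported flag) and the P450 regioselectivity
predictions (one row per predicted reaction site, M1–M8).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .adme import (
    CompoundRecord,
    MetabolitePrediction,
    read_compound_table,
    read_metabolite_table,
)

__all__ = [
    "load_reference_peaks",
    "load_reference_compounds",
    "load_reference_metabolites",
]

_DATA = resources.files("netpharm") / "data"


def load_reference_peaks() -> pd.DataFrame:
    """Ion-level view of the packaged compound table, one row per ion."""
    with resources.as_file(_DATA / "db_tablet_peaks.tsv") as path:
        return pd.read_csv(path, sep="\t", dtype=str)


def load_reference_compounds() -> list[CompoundRecord]:
    """Compound-level records (48 features; identified ones carry Papp)."""
    with resources.as_file(_DATA / "db_tablet_peaks.tsv") as path:
        return read_compound_table(path)


def load_reference_metabolites() -> list[MetabolitePrediction]:
    """P450 site predictions for metabolites M1–M8 (13 site rows)."""
    with resources.as_file(_DATA / "db_tablet_metabolites.tsv") as path:
        return read_metabolite_table(path)
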