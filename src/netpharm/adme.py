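"""ADME-based retention filters for constituents and predicted metabolites.

Two screens gate which chemical species enter the network stage:

* an absorption filter on the apparent Caco-2 permeability coefficient
  Papp (units of 1e-6 cm/s) — species above the cutoff are treated as
  orally absorbed.  The default cutoff of 7.0 follows the Yazdanian
  criterion for excellent oral absorption; 9.0 is a common stricter
  choice and both are plain parameters here.
* a credibility filter on P450 regioselectivity predictions — a
  metabolite is retained when at least one of its predicted reaction
  sites reaches both the score and the reliability cutoff.  Comparisons
  are inclusive (>=) so that boundary predictions (reliability exactly
  0.5) survive.

Both filters are idempotent and monotone in their thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .mass_annotation import ElementalFormula, parse_formula

__all__ = [
    "CompoundRecord",
    "MetabolitePrediction",
    "filter_absorbed",
    "filter_metabolites",
    "filter_summary",
    "read_compound_table",
    "read_metabolite_table",
]


@dataclass(frozen=True)
class CompoundRecord:
    """One chromatographic feature of the preparation.

    ``papp`` is the apparent permeability coefficient across a Caco-2
    monolayer in 1e-6 cm/s; ``None`` means no prediction is available
    (unidentified peaks).
    """

    id: int
    name: str
    formula: Optional[ElementalFormula] = None
    papp: Optional[float] = None
    previously_reported: bool = False

    def __post_init__(self) -> None:
        if self.papp is not None and self.papp < 0:
            raise ValueError(f"negative papp for compound {self.id}")


@dataclass(frozen=True)
class MetabolitePrediction:
    """One predicted P450 reaction site for a metabolite.

    A metabolite (``metabolite_id``) may own several rows, one per
    predicted reaction site.
    """

    metabolite_id: str
    parent_id: int
    score: float
    reliability: float
    reaction_site: int
    reaction_type: str
    enzyme: str
    parent_name: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score outside [0,1]: {self.score}")
        if not 0.0 <= self.reliability <= 1.0:
            raise ValueError(f"reliability outside [0,1]: {self.reliability}")


def filter_absorbed(
    compounds: Sequence[CompoundRecord], threshold: float = 7.0
) -> list[CompoundRecord]:
    """Retain compounds with Papp strictly above ``threshold``.

    Records lacking a Papp value are dropped; input order is preserved.
    ``threshold`` is in 1e-6 cm/s and must be positive.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    return [c for c in compounds if c.papp is not None and c.papp > threshold]


def filter_metabolites(
    predictions: Sequence[MetabolitePrediction],
    min_score: float = 0.6,
    min_reliability: float = 0.5,
) -> dict[str, list[MetabolitePrediction]]:
    """Retain metabolites with >= 1 site passing both cutoffs (inclusive).

    Returns a mapping metabolite_id -> its surviving rows, with ids in
    first-appearance order of the input.
    """
    for name, value in (("min_score", min_score),
                        ("min_reliability", min_reliability)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} outside [0,1]: {value}")
    retained: dict[str, list[MetabolitePrediction]] = {}
    for row in predictions:
        if row.score >= min_score and row.reliability >= min_reliability:
            retained.setdefault(row.metabolite_id, []).append(row)
    return retained


def filter_summary(n_input: int, n_retained: int, threshold) -> dict:
    """Uniform JSON-ready summary for either filter."""
    return {
        "n_input": n_input,
        "n_retained": n_retained,
        "threshold": threshold,
    }


# ---------------------------------------------------------------------------
# Tabular I/O


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    return float(text) if text else None


def _opt_str(value) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    return str(value).strip()


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read a compound table (TSV) into one record per compound id.

    Expected columns: ``no``, ``formula``, ``name``, ``papp``,
    ``previously_reported``; secondary ion rows of the same compound
    (same ``no``, blank name/papp) are collapsed onto the first row.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    records: list[CompoundRecord] = []
    seen: set[int] = set()
    for _, row in frame.iterrows():
        cid = int(row["no"])
        if cid in seen:
            continue
        seen.add(cid)
        name = _opt_str(row.get("name"))
        raw_formula = _opt_str(row.get("formula"))
        formula = parse_formula(raw_formula) if raw_formula else None
        prev = _opt_str(row.get("previously_reported")).lower() in (
            "yes", "true", "1"
        )
        records.append(
            CompoundRecord(
                id=cid,
                name=name or "unknown",
                formula=formula,
                papp=_opt_float(row.get("papp")),
                previously_reported=prev,
            )
        )
    return records


def read_metabolite_table(path: str | Path) -> list[MetabolitePrediction]:
    """Read a metabolite-prediction table (TSV), one row per site."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    rows: list[MetabolitePrediction] = []
    for _, row in frame.iterrows():
        rows.append(
            MetabolitePrediction(
                metabolite_id=str(row["metabolite_id"]).strip(),
                parent_id=int(row["parent_id"]),
                score=float(row["score"]),
                reliability=float(row["reliability"]),
                reaction_site=int(row["reaction_site"]),
                reaction_type=str(row["reaction_type"]).strip(),
                enzyme=str(row["enzyme"]).strip(),
                parent_name=str(row.get("parent_name", "")).strip(),
            )
        )
    return rows


def write_compound_table(
    compounds: Iterable[CompoundRecord], path: str | Path
) -> None:
    frame = pd.DataFrame(
        [
            {
                "no": c.id,
                "formula": str(c.formula) if c.formula else "",
                "name": c.name,
                "papp": c.papp if c.papp is not None else "",
                "previously_reported": "yes" if c.previously_reported else "no",
            }
            for c in compounds
        ]
    )
    frame.to_csv(path, sep="\t", index=False)
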