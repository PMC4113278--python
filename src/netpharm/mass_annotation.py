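"""Accurate-mass adduct annotation of LC-MS peaks.

Given an elemental formula, compute its neutral monoisotopic mass and the
m/z of its singly charged quasi-molecular ions ([M+H]+, [M-H]-, [M+Na]+,
[M+CH3COO]-); given a measured m/z, annotate it with the candidate
formulas whose best adduct falls within a ppm tolerance.  Ambiguities
between isobaric candidates are broken by a prior flag (compounds
previously reported in the preparation rank first), then by absolute ppm
error, then by compound id.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from .constants import (
    ADDUCT_MASS_DELTA,
    ADDUCT_POLARITY,
    MONOISOTOPIC_MASS,
)

__all__ = [
    "FormulaError",
    "ElementalFormula",
    "AdductSpec",
    "PeakAnnotation",
    "STANDARD_ADDUCTS",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "annotate_peak",
    "format_mz",
]


class FormulaError(ValueError):
    """Raised for formulas with unknown elements or malformed tokens."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

# Unicode minus / prime variants that appear in published tables.
_CLEAN = str.maketrans({"_": "", " ": "", "−": "-", "–": "-"})


@dataclass(frozen=True)
class ElementalFormula:
    """An elemental composition as an immutable (element, count) tuple.

    Element order is Hill convention: C first, then H, then the remaining
    symbols alphabetically (all alphabetical when no carbon), so that
    parse → serialize is idempotent.
    """

    items: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        for symbol, count in self.items:
            if symbol not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {symbol!r}")
            if count < 1:
                raise FormulaError(f"non-positive count for {symbol}: {count}")
        object.__setattr__(self, "items", _hill_sorted(dict(self.items)))

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "ElementalFormula":
        return cls(tuple(counts.items()))

    @property
    def element_counts(self) -> dict[str, int]:
        return dict(self.items)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = self.element_counts
        for symbol, count in other.items:
            merged[symbol] = merged.get(symbol, 0) + count
        return ElementalFormula.from_counts(merged)

    def __str__(self) -> str:
        return "".join(
            f"{s}{c if c != 1 else ''}" for s, c in self.items
        )


def _hill_sorted(counts: Mapping[str, int]) -> tuple[tuple[str, int], ...]:
    symbols = set(counts)
    if "C" in symbols:
        order = ["C"] + (["H"] if "H" in symbols else [])
        order += sorted(symbols - {"C", "H"})
    else:
        order = sorted(symbols)
    return tuple((s, counts[s]) for s in order)


def parse_formula(text: str) -> ElementalFormula:
    """Parse a molecular-formula string into an :class:`ElementalFormula`.

    Underscores and spaces are tolerated ("C_18_H_20_O_5" == "C18H20O5");
    an implicit count of 1 is expanded; a symbol occurring twice (as in
    "CH3COO") has its counts summed.

    Raises
    ------
    FormulaError
        If the string is empty, contains an unknown element symbol, an
        explicit zero count, or characters that do not form element
        tokens; the message names the offending token.
    """
    cleaned = text.translate(_CLEAN)
    if not cleaned:
        raise FormulaError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(cleaned):
        match = _TOKEN.match(cleaned, pos)
        if match is None or match.start() != pos or not match.group(1):
            raise FormulaError(
                f"malformed token at {cleaned[pos:]!r} in formula {text!r}"
            )
        symbol, digits = match.groups()
        if symbol not in MONOISOTOPIC_MASS:
            raise FormulaError(
                f"unknown element symbol {symbol!r} in formula {text!r}"
            )
        count = int(digits) if digits else 1
        if count < 1:
            raise FormulaError(
                f"zero count for element {symbol!r} in formula {text!r}"
            )
        counts[symbol] = counts.get(symbol, 0) + count
        pos = match.end()
    return ElementalFormula.from_counts(counts)


def monoisotopic_mass(formula: ElementalFormula | Mapping[str, int]) -> float:
    """Neutral monoisotopic mass in Da: sum of count x atomic mass.

    An empty composition is permitted and weighs 0.0.
    """
    counts = (
        formula.element_counts
        if isinstance(formula, ElementalFormula)
        else dict(formula)
    )
    mass = 0.0
    for symbol, count in counts.items():
        if symbol not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol: {symbol!r}")
        mass += count * MONOISOTOPIC_MASS[symbol]
    return mass


@dataclass(frozen=True)
class AdductSpec:
    """A singly charged quasi-molecular ion.

    ``mass_delta`` (Th) is the offset applied to the neutral monoisotopic
    mass; charge carrier and electron mass are included.  Instances for
    the four standard adducts are pre-built in :data:`STANDARD_ADDUCTS`
    from the physical-constant table and should be looked up, not
    re-derived.
    """

    name: str
    polarity: str
    mass_delta: float

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"invalid polarity: {self.polarity!r}")
        if self.name.endswith("+") and self.polarity != "positive":
            raise ValueError(f"{self.name} must be positive-mode")
        if self.name.endswith("-") and self.polarity != "negative":
            raise ValueError(f"{self.name} must be negative-mode")


STANDARD_ADDUCTS: dict[str, AdductSpec] = {
    name: AdductSpec(name, ADDUCT_POLARITY[name], delta)
    for name, delta in ADDUCT_MASS_DELTA.items()
}


def adduct_mz(
    formula: ElementalFormula | str, adduct: AdductSpec | str
) -> float:
    """m/z (Th) of ``formula`` ionized as ``adduct``.

    ``adduct`` may be an :class:`AdductSpec` or the name of a standard
    adduct (unicode minus tolerated).
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    if isinstance(adduct, str):
        key = adduct.translate(_CLEAN)
        if key not in STANDARD_ADDUCTS:
            raise KeyError(
                f"unknown adduct {adduct!r}; standard adducts: "
                f"{sorted(STANDARD_ADDUCTS)}"
            )
        adduct = STANDARD_ADDUCTS[key]
    return monoisotopic_mass(formula) + adduct.mass_delta


def ppm_error(measured: float, expected: float) -> float:
    """Relative mass error in parts per million.

    (measured - expected) / expected * 1e6; ``expected`` must be > 0.
    """
    if expected <= 0:
        raise ValueError(f"expected m/z must be positive, got {expected}")
    return (measured - expected) / expected * 1e6


@dataclass(frozen=True)
class PeakAnnotation:
    """One retained (peak, candidate, adduct) match."""

    measured_mz: float
    compound_id: str
    formula: ElementalFormula
    adduct: str
    expected_mz: float
    ppm_error: float
    previously_reported: bool


def annotate_peak(
    measured_mz: float,
    polarity: str,
    candidates: Sequence[tuple[object, ElementalFormula | str, bool]],
    tolerance_ppm: float = 5.0,
    adducts: Iterable[AdductSpec] | None = None,
    isotope_filter: Callable[[PeakAnnotation], bool] | None = None,
) -> list[PeakAnnotation]:
    """Annotate one measured peak against candidate formulas.

    For each candidate ``(compound_id, formula, previously_reported)`` the
    best-matching adduct of the requested polarity is scored and the
    annotation retained when ``|ppm| <= tolerance_ppm``.  The returned
    list is ranked by (previously_reported desc, |ppm| asc, compound id
    asc) — a total order, so the result is invariant under permutation of
    the candidate list.  ``isotope_filter`` is a hook for isotope-pattern
    vetting of retained annotations; the default accepts everything.
    """
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    if polarity not in ("positive", "negative"):
        raise ValueError(f"invalid polarity: {polarity!r}")
    pool = list(adducts) if adducts is not None else list(
        STANDARD_ADDUCTS.values()
    )
    pool = [a for a in pool if a.polarity == polarity]
    if not pool:
        raise ValueError(f"no adducts available for {polarity} mode")

    retained: list[PeakAnnotation] = []
    for compound_id, formula, prior in candidates:
        if isinstance(formula, str):
            formula = parse_formula(formula)
        best: PeakAnnotation | None = None
        for adduct in pool:
            expected = monoisotopic_mass(formula) + adduct.mass_delta
            err = ppm_error(measured_mz, expected)
            if best is None or abs(err) < abs(best.ppm_error):
                best = PeakAnnotation(
                    measured_mz=measured_mz,
                    compound_id=str(compound_id),
                    formula=formula,
                    adduct=adduct.name,
                    expected_mz=expected,
                    ppm_error=err,
                    previously_reported=bool(prior),
                )
        assert best is not None
        if abs(best.ppm_error) <= tolerance_ppm:
            if isotope_filter is None or isotope_filter(best):
                retained.append(best)

    retained.sort(
        key=lambda a: (
            not a.previously_reported,
            abs(a.ppm_error),
            a.compound_id,
        )
    )
    return retained


def format_mz(value: float, decimals: int = 5) -> str:
    """Format an m/z for display: fixed decimals, round-half-even."""
    return f"{round(value, decimals):.{decimals}f}"
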