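"""Similarity-based target prediction against a drug library.

Compounds and metabolites are screened against a library of drugs with
known therapeutic targets.  Similarity is the Tanimoto (Jaccard)
coefficient over binary molecular fingerprints; a library drug counts as
a hit when its score is strictly greater than the threshold (default
0.85, i.e. "similar to very similar"), and the targets of all hit drugs
are pooled as putative targets of the preparation.

Fingerprint generation itself is out of scope — fingerprints arrive from
external cheminformatics tooling or from the synthetic generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Fingerprint",
    "SimilarityHit",
    "PutativeTargets",
    "tanimoto",
    "screen_similar_drugs",
    "collect_putative_targets",
    "read_fingerprints",
    "write_fingerprints",
    "read_target_map",
    "write_target_map",
]


@dataclass(frozen=True)
class Fingerprint:
    """A binary molecular fingerprint as a set of set-bit indices."""

    owner_id: str
    length: int
    bits: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", frozenset(self.bits))
        if self.length <= 0:
            raise ValueError(f"fingerprint length must be positive")
        bad = [b for b in self.bits if not 0 <= b < self.length]
        if bad:
            raise ValueError(
                f"bit indices out of range [0, {self.length}): {sorted(bad)[:5]}"
            )


@dataclass(frozen=True)
class SimilarityHit:
    compound_id: str
    drug_id: str
    score: float


@dataclass
class PutativeTargets:
    """Union of targets over hit drugs, plus the per-compound breakdown."""

    targets: set[str] = field(default_factory=set)
    per_compound: dict[str, set[str]] = field(default_factory=dict)
    missing_drugs: list[str] = field(default_factory=list)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B|; 1.0 when both sets are empty."""
    if a.length != b.length:
        raise ValueError(
            f"fingerprint length mismatch: {a.length} != {b.length}"
        )
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union


def screen_similar_drugs(
    compounds: Sequence[Fingerprint],
    library: Sequence[Fingerprint],
    threshold: float = 0.85,
) -> list[SimilarityHit]:
    """All (compound, drug) pairs with Tanimoto strictly above threshold.

    Sorted by (compound_id, score descending, drug_id).
    """
    if not library:
        raise ValueError("drug library must be non-empty")
    hits = [
        SimilarityHit(c.owner_id, d.owner_id, score)
        for c in compounds
        for d in library
        if (score := tanimoto(c, d)) > threshold
    ]
    hits.sort(key=lambda h: (h.compound_id, -h.score, h.drug_id))
    return hits


def collect_putative_targets(
    hits: Sequence[SimilarityHit],
    target_map: Mapping[str, Iterable[str]],
) -> PutativeTargets:
    """Union the target sets of all hit drugs.

    Hit drugs absent from ``target_map`` are skipped with a warning and
    listed in ``missing_drugs``.  Accessions are upper-cased.
    """
    result = PutativeTargets()
    for hit in hits:
        if hit.drug_id not in target_map:
            result.missing_drugs.append(hit.drug_id)
            continue
        targets = {str(t).upper() for t in target_map[hit.drug_id]}
        result.targets |= targets
        result.per_compound.setdefault(hit.compound_id, set()).update(targets)
    if result.missing_drugs:
        warnings.warn(
            f"{len(result.missing_drugs)} hit drug(s) missing from target map",
            stacklevel=2,
        )
    return result


# ---------------------------------------------------------------------------
# TSV I/O: (id, length, comma-separated bit indices) / (drug_id, accession)


def read_fingerprints(path: str | Path) -> list[Fingerprint]:
    fps = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            owner, length, bits = line.split("\t")
            indices = frozenset(
                int(b) for b in bits.split(",") if b.strip()
            )
            fps.append(Fingerprint(owner, int(length), indices))
    return fps


def write_fingerprints(fps: Iterable[Fingerprint], path: str | Path) -> None:
    with open(path, "w") as handle:
        for fp in fps:
            bits = ",".join(str(b) for b in sorted(fp.bits))
            handle.write(f"{fp.owner_id}\t{fp.length}\t{bits}\n")


def read_target_map(path: str | Path) -> dict[str, set[str]]:
    mapping: dict[str, set[str]] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            drug, accession = line.split("\t")
            mapping.setdefault(drug, set()).add(accession.upper())
    return mapping


def write_target_map(
    mapping: Mapping[str, Iterable[str]], path: str | Path
) -> None:
    with open(path, "w") as handle:
        for drug in sorted(mapping):
            for accession in sorted(mapping[drug]):
                handle.write(f"{drug}\t{accession}\n")
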