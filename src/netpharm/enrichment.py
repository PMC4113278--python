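"""Over-representation analysis of a target set against pathway gene sets.

For a query set of n proteins drawn from a background of N, and a
pathway with K members, the overlap k is scored with the one-sided
hypergeometric upper tail P(X >= k); p-values are adjusted across tested
pathways with Benjamini–Hochberg.  Gene sets travel in GMT format
(id <TAB> description <TAB> member ...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "hypergeometric_p",
    "enrich",
    "read_gmt",
    "write_gmt",
]


@dataclass(frozen=True)
class GeneSet:
    id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "members", frozenset(str(m).upper() for m in self.members)
        )
        if not self.members:
            raise ValueError(f"gene set {self.id} has no members")


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    pathway_name: str
    k: int        # overlap
    K: int        # pathway size within background
    n: int        # query size
    N: int        # background size
    p_value: float
    adjusted_p: float


def hypergeometric_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= n <= N):
        raise ValueError(f"need 0 <= k <= n <= N, got k={k}, n={n}, N={N}")
    if not (k <= K <= N):
        raise ValueError(f"need k <= K <= N, got k={k}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: Iterable[str],
    gene_sets: Sequence[GeneSet],
    background: Iterable[str] | None = None,
) -> list[EnrichmentResult]:
    """Rank gene sets by hypergeometric over-representation of ``query``.

    ``background`` defaults to the union of all gene-set members.  Query
    accessions outside the background are dropped with a warning.  Only
    sets with overlap k >= 1 are reported; BH adjustment is computed
    across all tested (k >= 1) sets, and results are sorted by ascending
    p-value then pathway id.
    """
    query = {str(q).upper() for q in query}
    if background is None:
        bg: set[str] = set()
        for gs in gene_sets:
            bg |= gs.members
    else:
        bg = {str(b).upper() for b in background}
    if not bg:
        raise ValueError("background is empty")
    stray = query - bg
    if stray:
        warnings.warn(
            f"{len(stray)} query accession(s) outside background dropped",
            stacklevel=2,
        )
        query &= bg

    N = len(bg)
    n = len(query)
    results: list[EnrichmentResult] = []
    for gs in gene_sets:
        members = gs.members & bg
        k = len(query & members)
        if k < 1:
            continue
        results.append(
            EnrichmentResult(
                pathway_id=gs.id,
                pathway_name=gs.name,
                k=k,
                K=len(members),
                n=n,
                N=N,
                p_value=hypergeometric_p(k, len(members), n, N),
                adjusted_p=1.0,  # filled below
            )
        )
    if results:
        _, adjusted, _, _ = multipletests(
            [r.p_value for r in results], method="fdr_bh"
        )
        results = [
            EnrichmentResult(
                r.pathway_id, r.pathway_name, r.k, r.K, r.n, r.N,
                r.p_value, float(p_adj),
            )
            for r, p_adj in zip(results, adjusted)
        ]
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    return results


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            sets.append(
                GeneSet(fields[0], fields[1], frozenset(fields[2:]))
            )
    return sets


def write_gmt(gene_sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as handle:
        for gs in gene_sets:
            members = "\t".join(sorted(gs.members))
            handle.write(f"{gs.id}\t{gs.name}\t{members}\n")
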