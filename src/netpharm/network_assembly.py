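"""Assembly of the compound–target bipartite and merged PPI networks.

Three constructions:

* the bipartite network linking absorbed constituents/metabolites to
  their putative protein targets, with the summary statistic "mean
  putative targets per chemical node" = |targets| / |chemicals|;
* a merged simple undirected PPI graph from several tagged edge lists
  (TSV or SIF), with self-loops dropped, duplicates collapsed under a
  union of source tags, and optional table-driven accession
  normalization;
* the target sub-network: the subgraph induced on the putative targets,
  the known therapeutic targets, and their first neighbors (radius
  configurable), with node roles annotated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "BipartiteStats",
    "MergeReport",
    "build_bipartite",
    "merge_ppi",
    "read_edge_file",
    "extract_target_network",
    "write_sif",
    "write_graphml",
]


@dataclass(frozen=True)
class BipartiteStats:
    n_compound_nodes: int
    n_target_nodes: int
    n_nodes: int
    n_edges: int
    #: |target nodes| / |compound nodes|, rounded to 2 decimals
    targets_per_chemical: float


def build_bipartite(
    per_compound_targets: Mapping[str, Iterable[str]],
) -> tuple[nx.Graph, BipartiteStats]:
    """Build the compound–target bipartite network with its statistics.

    Keys are chemical nodes (compounds or metabolites), values their
    putative target accessions.  A chemical id colliding with a target
    accession is an error, since node type would be ambiguous.
    """
    if not per_compound_targets:
        raise ValueError("per_compound_targets must be non-empty")
    graph = nx.Graph()
    compounds = [str(c) for c in per_compound_targets]
    targets: set[str] = set()
    for compound, accs in per_compound_targets.items():
        graph.add_node(str(compound), kind="compound")
        for acc in accs:
            targets.add(str(acc))
    overlap = set(compounds) & targets
    if overlap:
        raise ValueError(
            f"ids appear as both chemical and target: {sorted(overlap)[:5]}"
        )
    for acc in targets:
        graph.add_node(acc, kind="target")
    for compound, accs in per_compound_targets.items():
        for acc in accs:
            graph.add_edge(str(compound), str(acc))
    stats = BipartiteStats(
        n_compound_nodes=len(compounds),
        n_target_nodes=len(targets),
        n_nodes=len(compounds) + len(targets),
        n_edges=graph.number_of_edges(),
        targets_per_chemical=round(len(targets) / len(compounds), 2),
    )
    return graph, stats


@dataclass
class MergeReport:
    n_input_edges: int = 0
    n_self_loops: int = 0
    n_duplicate_edges: int = 0
    n_malformed: dict[str, int] = field(default_factory=dict)
    unmapped_ids: set[str] = field(default_factory=set)


def read_edge_file(path: str | Path) -> list[tuple[str, str]]:
    """Read an undirected edge list from TSV (a<TAB>b) or SIF.

    SIF lines are ``a interaction b1 [b2 ...]``; files ending in ``.sif``
    (or whitespace-delimited 3+-column lines) are treated as SIF.
    Malformed lines raise only if they are the majority of the file.
    """
    path = Path(path)
    is_sif = path.suffix.lower() == ".sif"
    edges: list[tuple[str, str]] = []
    n_bad = 0
    n_lines = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            n_lines += 1
            fields = line.split("\t") if "\t" in line else line.split()
            if is_sif or len(fields) >= 3:
                if len(fields) < 3:
                    n_bad += 1
                    warnings.warn(f"{path}:{lineno}: malformed SIF line")
                    continue
                edges.extend((fields[0], b) for b in fields[2:])
            elif len(fields) == 2:
                edges.append((fields[0], fields[1]))
            else:
                n_bad += 1
                warnings.warn(f"{path}:{lineno}: malformed edge line")
    if n_lines and n_bad > n_lines / 2:
        raise ValueError(f"{path}: {n_bad}/{n_lines} lines malformed")
    return edges


def merge_ppi(
    sources: Mapping[str, str | Path | Iterable[tuple[str, str]]],
    id_map: Mapping[str, str] | None = None,
) -> tuple[nx.Graph, MergeReport]:
    """Merge tagged PPI edge lists into one simple undirected graph.

    ``sources`` maps a database tag (e.g. "HPRD") to a file path or an
    in-memory iterable of (a, b) pairs.  Accessions are normalized via
    ``id_map`` when given; ids missing from the map are kept verbatim
    and reported.  Self-loops (after normalization) are dropped and
    duplicate edges collapsed, with each edge carrying the union of its
    source tags in the ``sources`` edge attribute.
    """
    graph = nx.Graph()
    report = MergeReport()
    for tag, source in sources.items():
        if isinstance(source, (str, Path)):
            edges = read_edge_file(source)
        else:
            edges = list(source)
        for a, b in edges:
            report.n_input_edges += 1
            if id_map is not None:
                for raw in (a, b):
                    if raw not in id_map:
                        report.unmapped_ids.add(raw)
                a = id_map.get(a, a)
                b = id_map.get(b, b)
            a, b = str(a).upper(), str(b).upper()
            if a == b:
                report.n_self_loops += 1
                continue
            if graph.has_edge(a, b):
                report.n_duplicate_edges += 1
                graph.edges[a, b]["sources"].add(tag)
            else:
                graph.add_edge(a, b, sources={tag})
    return graph, report


def extract_target_network(
    ppi: nx.Graph,
    putative: Iterable[str],
    known: Iterable[str],
    radius: int = 1,
) -> tuple[nx.Graph, dict]:
    """Induced subgraph on targets plus their radius-1 interactors.

    Node roles are annotated as ``putative``, ``known``, ``both`` or
    ``interactor``.  Seed targets that are isolated in the PPI graph are
    retained as isolated nodes; seeds absent from the graph entirely are
    reported in the returned summary, not fatal.
    """
    putative = {str(p).upper() for p in putative}
    known = {str(k).upper() for k in known}
    seeds = putative | known
    present = seeds & set(ppi.nodes)
    missing = sorted(seeds - present)
    keep = set(present)
    for seed in present:
        reached = nx.single_source_shortest_path_length(
            ppi, seed, cutoff=radius
        )
        keep.update(reached)
    sub = ppi.subgraph(keep).copy()
    for node in sub.nodes:
        if node in putative and node in known:
            role = "both"
        elif node in putative:
            role = "putative"
        elif node in known:
            role = "known"
        else:
            role = "interactor"
        sub.nodes[node]["role"] = role
    summary = {
        "n_nodes": sub.number_of_nodes(),
        "n_edges": sub.number_of_edges(),
        "n_putative_present": len(putative & present),
        "n_known_present": len(known & present),
        "missing_targets": missing,
    }
    return sub, summary


def write_sif(
    graph: nx.Graph, path: str | Path, interaction: str = "pp"
) -> None:
    with open(path, "w") as handle:
        for a, b in sorted(map(lambda e: tuple(sorted(e)), graph.edges())):
            handle.write(f"{a}\t{interaction}\t{b}\n")
        for node in sorted(nx.isolates(graph)):
            handle.write(f"{node}\n")


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    """GraphML export; set-valued attributes become sorted CSV strings."""
    export = graph.copy()
    for _, _, data in export.edges(data=True):
        if isinstance(data.get("sources"), set):
            data["sources"] = ",".join(sorted(data["sources"]))
    nx.write_graphml(export, path)
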