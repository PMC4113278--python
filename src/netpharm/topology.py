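"""Per-node topology measures and median-based hub screening.

Four measures are computed on simple undirected graphs:

* degree;
* betweenness — the number of shortest (s, t) paths through a node,
  summed over unordered pairs with the node excluded as endpoint.
  Reported raw and normalized by (N-1)(N-2)/2, the number of pairs;
* closeness — literally the inverse of the summed distances from the
  node to all others in its connected component (1/Σd), plus the
  conventional scaled variant (n_comp - 1)/Σd.  Isolated nodes score 0;
* k value — the largest k for which the node survives iterative deletion
  of vertices of degree < k (its core number).

Hub screening: a node is a hub when its degree strictly exceeds twice
the median degree of the whole network.  Major hubs are found on the
hub-induced subgraph: recompute all four measures there, take the
per-measure medians over hub nodes, and keep the hubs strictly above all
four medians (explicit thresholds can be injected instead).  Medians use
the midpoint convention for even counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, NamedTuple

import networkx as nx
import pandas as pd

__all__ = [
    "Betweenness",
    "Closeness",
    "HubScreen",
    "betweenness",
    "closeness",
    "k_core",
    "node_topology_table",
    "identify_hubs",
    "identify_major_hubs",
]


class Betweenness(NamedTuple):
    raw: float
    normalized: float


class Closeness(NamedTuple):
    literal: float   # 1 / sum of distances within the component
    scaled: float    # (n_component - 1) / sum of distances


def betweenness(graph: nx.Graph) -> dict[object, Betweenness]:
    """Raw and pair-normalized betweenness for every node.

    Disconnected (s, t) pairs contribute nothing; graphs with fewer than
    three nodes have normalized value 0 by convention.
    """
    raw = nx.betweenness_centrality(graph, normalized=False)
    n = graph.number_of_nodes()
    pairs = (n - 1) * (n - 2) / 2
    return {
        node: Betweenness(value, value / pairs if pairs > 0 else 0.0)
        for node, value in raw.items()
    }


def closeness(graph: nx.Graph) -> dict[object, Closeness]:
    """Literal (1/Σd) and scaled ((n_comp-1)/Σd) closeness per node."""
    out: dict[object, Closeness] = {}
    for node in graph.nodes:
        lengths = nx.single_source_shortest_path_length(graph, node)
        total = sum(lengths.values())  # distance to self is 0
        n_reached = len(lengths) - 1
        if total == 0:
            out[node] = Closeness(0.0, 0.0)
        else:
            out[node] = Closeness(1.0 / total, n_reached / total)
    return out


def k_core(graph: nx.Graph) -> dict[object, int]:
    """Core number of every node (0 for isolated nodes)."""
    stripped = graph.copy()
    stripped.remove_edges_from(nx.selfloop_edges(stripped))
    return nx.core_number(stripped)


def node_topology_table(graph: nx.Graph) -> pd.DataFrame:
    """All four measures as a DataFrame indexed by node."""
    btw = betweenness(graph)
    cls = closeness(graph)
    core = k_core(graph)
    rows = {
        node: {
            "degree": graph.degree(node),
            "betweenness_raw": btw[node].raw,
            "betweenness_norm": btw[node].normalized,
            "closeness": cls[node].literal,
            "closeness_scaled": cls[node].scaled,
            "k_value": core[node],
        }
        for node in graph.nodes
    }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "node"
    return frame


@dataclass
class HubScreen:
    """Result of the hub and major-hub screens."""

    median_degree: float
    hub_factor: float
    hubs: set = field(default_factory=set)
    #: per-measure thresholds used for the major-hub screen
    thresholds: dict[str, float] = field(default_factory=dict)
    major_hubs: set = field(default_factory=set)
    #: four-measure table on the hub-induced subgraph
    hub_table: pd.DataFrame | None = None


def identify_hubs(graph: nx.Graph, factor: float = 2.0) -> HubScreen:
    """Nodes whose degree strictly exceeds ``factor`` x median degree."""
    if graph.number_of_nodes() == 0:
        raise ValueError("graph must be non-empty")
    degrees = dict(graph.degree())
    med = median(degrees.values())
    hubs = {n for n, d in degrees.items() if d > factor * med}
    return HubScreen(median_degree=med, hub_factor=factor, hubs=hubs)


def identify_major_hubs(
    graph: nx.Graph,
    screen: HubScreen | Iterable | None = None,
    betweenness_variant: str = "normalized",
    closeness_variant: str = "literal",
    thresholds: Mapping[str, float] | None = None,
) -> HubScreen:
    """Screen hubs for major hubs on the hub-induced subgraph.

    The four measures are recomputed on the subgraph induced by the hub
    set (not inherited from the parent network).  Default thresholds are
    the per-measure medians over the hub nodes; ``thresholds`` overrides
    any of ``degree``, ``betweenness``, ``closeness``, ``k_value`` with
    literal cutoffs.  A hub is major iff strictly greater on all four.
    """
    if screen is None:
        screen = identify_hubs(graph)
    elif not isinstance(screen, HubScreen):
        hubs = set(screen)
        if not hubs <= set(graph.nodes):
            raise ValueError("hub set must be a subset of graph nodes")
        screen = HubScreen(
            median_degree=median(d for _, d in graph.degree()),
            hub_factor=float("nan"),
            hubs=hubs,
        )
    if betweenness_variant not in ("raw", "normalized"):
        raise ValueError(f"bad betweenness variant: {betweenness_variant!r}")
    if closeness_variant not in ("literal", "scaled"):
        raise ValueError(f"bad closeness variant: {closeness_variant!r}")
    if not screen.hubs:
        screen.hub_table = pd.DataFrame()
        return screen

    sub = graph.subgraph(screen.hubs).copy()
    table = node_topology_table(sub)
    columns = {
        "degree": "degree",
        "betweenness": (
            "betweenness_raw"
            if betweenness_variant == "raw"
            else "betweenness_norm"
        ),
        "closeness": (
            "closeness" if closeness_variant == "literal" else "closeness_scaled"
        ),
        "k_value": "k_value",
    }
    cutoffs = {
        measure: median(table[column]) for measure, column in columns.items()
    }
    if thresholds:
        unknown = set(thresholds) - set(cutoffs)
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        cutoffs.update(thresholds)
    major = {
        node
        for node in table.index
        if all(
            table.at[node, column] > cutoffs[measure]
            for measure, column in columns.items()
        )
    }
    screen.thresholds = cutoffs
    screen.major_hubs = major
    screen.hub_table = table
    return screen
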