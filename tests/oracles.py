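"""Independent brute-force oracles used by the test suite.

Everything here works on plain adjacency dicts and exhaustive
enumeration — no networkx, no scipy — so agreement with the package is
a genuine cross-check, not a tautology.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def to_adjacency(edges, nodes=None) -> dict:
    adj: dict = {n: set() for n in (nodes or [])}
    for a, b in edges:
        adj.setdefault(a, set())
        adj.setdefault(b, set())
        if a != b:
            adj[a].add(b)
            adj[b].add(a)
    return adj


def _all_simple_paths(adj, source, sink):
    paths = []
    stack = [source]

    def dfs(node):
        if node == sink:
            paths.append(list(stack))
            return
        for neighbor in sorted(adj[node]):
            if neighbor not in stack:
                stack.append(neighbor)
                dfs(neighbor)
                stack.pop()

    dfs(source)
    return paths


def brute_betweenness(adj) -> dict:
    """Raw betweenness by exhaustive shortest-path enumeration."""
    nodes = sorted(adj)
    values = {n: Fraction(0) for n in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_simple_paths(adj, s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        geodesics = [p for p in paths if len(p) == shortest]
        sigma = len(geodesics)
        for i in nodes:
            if i in (s, t):
                continue
            through = sum(1 for p in geodesics if i in p)
            values[i] += Fraction(through, sigma)
    return {n: float(v) for n, v in values.items()}


def brute_distances(adj) -> dict:
    """All-pairs shortest-path lengths by Floyd–Warshall."""
    nodes = sorted(adj)
    dist = {
        (a, b): (0 if a == b else (1 if b in adj[a] else math.inf))
        for a in nodes
        for b in nodes
    }
    for k in nodes:
        for a in nodes:
            for b in nodes:
                via = dist[a, k] + dist[k, b]
                if via < dist[a, b]:
                    dist[a, b] = via
    return dist


def brute_closeness(adj) -> dict:
    """Literal closeness 1/Σd within the node's component."""
    dist = brute_distances(adj)
    out = {}
    for node in adj:
        total = sum(
            d for (a, b), d in dist.items()
            if a == node and b != node and d < math.inf
        )
        out[node] = 0.0 if total == 0 else 1.0 / total
    return out


def brute_k_values(adj) -> dict:
    """k value per node by direct simulation of iterative deletion."""
    out = {n: 0 for n in adj}
    max_degree = max((len(v) for v in adj.values()), default=0)
    for k in range(max_degree + 2):
        survivors = {n: set(v) for n, v in adj.items()}
        changed = True
        while changed:
            changed = False
            for node in list(survivors):
                if len(survivors[node]) < k:
                    for nb in survivors.pop(node):
                        survivors[nb].discard(node)
                    changed = True
        for node in survivors:
            out[node] = k
    return out


def brute_median(values):
    """Midpoint-convention median on a fresh sorted copy."""
    ordered = sorted(values)
    n = len(ordered)
    mid = n // 2
    if n % 2:
        return ordered[mid]
    return (ordered[mid - 1] + ordered[mid]) / 2


def brute_hypergeometric_upper(k, K, n, N) -> Fraction:
    """P(X >= k) by enumerating all C(N, n) draws."""
    hits = 0
    total = 0
    population = list(range(N))
    marked = set(range(K))
    for draw in itertools.combinations(population, n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return Fraction(hits, total)


def random_graph_edges(rng, n, p):
    """Erdős–Rényi G(n, p) edge list from a numpy Generator."""
    nodes = list(range(n))
    return [
        (a, b)
        for a, b in itertools.combinations(nodes, 2)
        if rng.random() < p
    ], nodes
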