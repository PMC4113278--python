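"""Synthetic inputs with planted, machine-checkable structure.

Real counterparts of the pipeline inputs — vendor ADME predictions, a
commercial drug-similarity library, and the eight-database interactome
snapshots — are not redistributable, so every stage can instead be fed
from this module.  Each generator emulates the statistical structure the
analysis assumes and records the planted ground truth in a manifest:

* compound tables with log-normal Papp straddling the absorption cutoff
  (the exceedance probability at the cutoff is known analytically);
* scale-free PPI graphs (preferential attachment) with planted hub
  nodes wired to exceed twice the realized median degree by a margin;
* drug libraries where each query compound has exactly one planted
  near-duplicate whose Jaccard similarity is hit exactly by bit-count
  arithmetic, with all baseline drugs far below the screening threshold;
* gene-set collections with one planted over-represented pathway from
  which the query is preferentially sampled.

All randomness flows from ``SimConfig.seed`` through a fixed
``SeedSequence`` spawn order, so a given configuration reproduces its
outputs byte-for-byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from fractions import Fraction
from pathlib import Path

import networkx as nx
import numpy as np

from .adme import CompoundRecord, MetabolitePrediction
from .enrichment import GeneSet, write_gmt
from .target_prediction import (
    Fingerprint,
    write_fingerprints,
    write_target_map,
)

__all__ = [
    "SimConfig",
    "gen_compound_table",
    "gen_metabolite_table",
    "gen_ppi_network",
    "gen_drug_library",
    "gen_gene_sets",
    "write_bundle",
]

# Fixed spawn keys: the child RNG for each generator never depends on
# which other generators ran.
_STREAMS = {
    "compounds": 0,
    "metabolites": 1,
    "ppi": 2,
    "library": 3,
    "gene_sets": 4,
}


@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults for all generators.

    Defaults mirror the reference study: 48 chromatographic features,
    Papp log-normal with median at the 7.0 (1e-6 cm/s) absorption
    cutoff, an interactome of 2397 proteins grown by preferential
    attachment with 2 edges per arriving node, and a similarity library
    whose planted near-duplicates sit at Jaccard 0.9 (exactly 90 shared
    of 100 united bits for 95-bit fingerprints).
    """

    seed: int = 0
    # compound table / Papp
    n_compounds: int = 48
    papp_mu: float = math.log(7.0)   # ln Papp mean; median exp(mu)
    papp_sigma: float = 1.5
    papp_threshold: float = 7.0      # recorded in the manifest
    # metabolite predictions
    n_metabolite_rows: int = 13
    # PPI graph
    n_proteins: int = 2397
    attachment_edges_per_node: int = 2
    planted_hub_count: int = 5
    hub_degree_margin: float = 0.5   # exceed 2x median by this fraction
    hub_factor: float = 2.0
    # drug library
    n_query_compounds: int = 30
    library_size: int = 200
    fp_length: int = 1024
    fp_bits: int = 95
    planted_similarity: float = 0.9
    targets_per_drug: int = 2
    target_pool_size: int = 500
    # gene sets
    n_pathways: int = 50
    set_size: int = 40
    universe_size: int = 2000
    query_size: int = 25
    enrichment_effect: float = 0.8

    def __post_init__(self) -> None:
        for name in (
            "n_compounds", "n_metabolite_rows", "n_proteins",
            "attachment_edges_per_node", "library_size", "fp_length",
            "fp_bits", "n_pathways", "set_size", "universe_size",
            "query_size", "target_pool_size",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.enrichment_effect <= 1.0:
            raise ValueError("enrichment_effect must be in [0,1]")
        if not 0.0 < self.planted_similarity <= 1.0:
            raise ValueError("planted_similarity must be in (0,1]")

    def rng(self, stream: str) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.default_rng(children[_STREAMS[stream]])


def _accession(prefix: str, index: int) -> str:
    return f"{prefix}{index:05d}"


def gen_compound_table(
    config: SimConfig,
) -> tuple[list[CompoundRecord], dict]:
    """Compounds with log-normal Papp; manifest records the exceedance.

    P(Papp > t) = 1 - Phi((ln t - mu) / sigma); with the defaults the
    cutoff sits at the log-normal median, so half the table is retained
    in expectation.
    """
    rng = config.rng("compounds")
    papp = rng.lognormal(config.papp_mu, config.papp_sigma, config.n_compounds)
    records = [
        CompoundRecord(
            id=i + 1,
            name=f"SYN-{i + 1:04d}",
            papp=float(papp[i]),
        )
        for i in range(config.n_compounds)
    ]
    t = config.papp_threshold
    if config.papp_sigma > 0:
        z = (math.log(t) - config.papp_mu) / config.papp_sigma
        exceedance = 1.0 - 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))
    else:
        exceedance = float(math.exp(config.papp_mu) > t)
    realized = (
        sum(r.papp > t for r in records) / len(records) if records else 0.0
    )
    manifest = {
        "seed": config.seed,
        "n": config.n_compounds,
        "threshold": t,
        "exceedance_probability": exceedance,
        "realized_fraction": realized,
    }
    return records, manifest


def gen_metabolite_table(
    config: SimConfig,
) -> tuple[list[MetabolitePrediction], dict]:
    """Uniform score/reliability site predictions for synthetic parents."""
    rng = config.rng("metabolites")
    rows = []
    for i in range(config.n_metabolite_rows):
        rows.append(
            MetabolitePrediction(
                metabolite_id=f"M{(i % max(config.n_metabolite_rows // 2, 1)) + 1}",
                parent_id=int(rng.integers(1, max(config.n_compounds, 2))),
                score=float(rng.uniform()),
                reliability=float(rng.uniform()),
                reaction_site=int(rng.integers(1, 30)),
                reaction_type="Aromatic Hydroxylation",
                enzyme="CYP1A2",
            )
        )
    manifest = {"seed": config.seed, "n_rows": len(rows)}
    return rows, manifest


def gen_ppi_network(config: SimConfig) -> tuple[nx.Graph, dict]:
    """Preferential-attachment PPI graph with margin-guaranteed hubs.

    The base graph grows by ``attachment_edges_per_node`` (m) edges per
    arriving node after an m-node edgeless seed, giving (n - m) * m
    edges.  Planted hubs are appended afterwards and wired to random
    hosts until each strictly exceeds ``hub_factor`` x the realized
    median degree by the configured relative margin, so a median-based
    hub screen must recover them.
    """
    m = config.attachment_edges_per_node
    rng = config.rng("ppi")
    base_seed = int(rng.integers(0, 2**31 - 1))
    graph = nx.barabasi_albert_graph(config.n_proteins, m, seed=base_seed)
    graph = nx.relabel_nodes(
        graph, {i: _accession("SYNP", i) for i in graph.nodes}
    )
    planted = [
        _accession("HUB", i) for i in range(config.planted_hub_count)
    ]
    hosts = sorted(graph.nodes)
    from statistics import median as _median

    for hub in planted:
        graph.add_node(hub)
    changed = True
    while changed and planted:
        changed = False
        med = _median(d for _, d in graph.degree())
        target = config.hub_factor * med * (1.0 + config.hub_degree_margin)
        for hub in planted:
            while graph.degree(hub) <= target:
                candidates = [
                    h for h in hosts if not graph.has_edge(hub, h)
                ]
                if not candidates:
                    break
                pick = candidates[int(rng.integers(0, len(candidates)))]
                graph.add_edge(hub, pick)
                changed = True
    med = _median(d for _, d in graph.degree()) if graph else 0
    manifest = {
        "seed": config.seed,
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "planted_hubs": planted,
        "planted_degrees": {h: graph.degree(h) for h in planted},
        "median_degree": med,
        "hub_factor": config.hub_factor,
        "margin": config.hub_degree_margin,
    }
    return graph, manifest


def _planted_overlap(bits: int, similarity: float) -> int:
    """Intersection size making Jaccard exactly ``similarity``.

    For two equal-size bit sets of ``bits`` bits sharing i, the Jaccard
    index is i / (2*bits - i); solving gives i = 2*bits*s / (1 + s),
    which must be an integer for the similarity to be realizable.
    """
    s = Fraction(similarity).limit_denominator(10**6)
    i = Fraction(2 * bits) * s / (1 + s)
    if i.denominator != 1:
        raise ValueError(
            f"planted similarity {similarity} not realizable with "
            f"{bits}-bit fingerprints (needs intersection {float(i):.3f})"
        )
    return int(i)


def gen_drug_library(
    config: SimConfig,
) -> tuple[list[Fingerprint], list[Fingerprint], dict[str, set[str]], dict]:
    """Query fingerprints, a drug library, and the drug→target map.

    Each query compound gets exactly one planted library drug whose
    Jaccard similarity equals ``planted_similarity`` by construction;
    the remaining drugs are independent random bit sets whose expected
    similarity to anything is far below the 0.85 screening threshold.
    """
    rng = config.rng("library")
    L, b = config.fp_length, config.fp_bits
    if b > L:
        raise ValueError("fp_bits cannot exceed fp_length")
    i_shared = _planted_overlap(b, config.planted_similarity)

    queries: list[Fingerprint] = []
    library: list[Fingerprint] = []
    target_map: dict[str, set[str]] = {}
    planted_pairs: list[tuple[str, str]] = []
    pool = [_accession("P", i) for i in range(config.target_pool_size)]

    for q in range(config.n_query_compounds):
        qid = f"CMP-{q + 1:04d}"
        bits = rng.choice(L, size=b, replace=False)
        queries.append(Fingerprint(qid, L, frozenset(int(x) for x in bits)))
        did = f"DRUG-P{q + 1:04d}"
        keep = rng.choice(b, size=i_shared, replace=False)
        kept = {int(bits[j]) for j in keep}
        outside = np.setdiff1d(np.arange(L), bits, assume_unique=False)
        fresh = rng.choice(outside, size=b - i_shared, replace=False)
        drug_bits = kept | {int(x) for x in fresh}
        library.append(Fingerprint(did, L, frozenset(drug_bits)))
        planted_pairs.append((qid, did))
        n_t = int(rng.integers(1, config.targets_per_drug + 1))
        target_map[did] = {
            pool[int(j)] for j in rng.choice(len(pool), n_t, replace=False)
        }

    for d in range(config.library_size - config.n_query_compounds):
        did = f"DRUG-B{d + 1:04d}"
        bits = rng.choice(L, size=b, replace=False)
        library.append(Fingerprint(did, L, frozenset(int(x) for x in bits)))
        n_t = int(rng.integers(1, config.targets_per_drug + 1))
        target_map[did] = {
            pool[int(j)] for j in rng.choice(len(pool), n_t, replace=False)
        }

    manifest = {
        "seed": config.seed,
        "planted_similarity": config.planted_similarity,
        "planted_intersection": i_shared,
        "planted_union": 2 * b - i_shared,
        "planted_pairs": planted_pairs,
        "n_library": len(library),
    }
    return queries, library, target_map, manifest


def gen_gene_sets(
    config: SimConfig,
) -> tuple[list[GeneSet], set[str], dict]:
    """Gene sets with one planted over-represented pathway and a query.

    round(effect x query_size) query members come from the planted set,
    the rest uniformly from the remainder of the universe.
    """
    rng = config.rng("gene_sets")
    universe = [_accession("P", i) for i in range(config.universe_size)]
    sets: list[GeneSet] = []
    for p in range(config.n_pathways):
        members = rng.choice(
            config.universe_size, size=config.set_size, replace=False
        )
        sets.append(
            GeneSet(
                id=f"pw{p + 1:04d}",
                name=f"synthetic pathway {p + 1}",
                members=frozenset(universe[int(j)] for j in members),
            )
        )
    planted_index = int(rng.integers(0, config.n_pathways))
    planted = sets[planted_index]
    n_from_planted = min(
        round(config.enrichment_effect * config.query_size),
        len(planted.members),
    )
    members_sorted = sorted(planted.members)
    inside = rng.choice(
        len(members_sorted), size=n_from_planted, replace=False
    )
    query = {members_sorted[int(j)] for j in inside}
    outside_pool = sorted(set(universe) - planted.members)
    n_outside = config.query_size - n_from_planted
    outside = rng.choice(len(outside_pool), size=n_outside, replace=False)
    query |= {outside_pool[int(j)] for j in outside}
    manifest = {
        "seed": config.seed,
        "planted_pathway": planted.id,
        "n_from_planted": n_from_planted,
        "query_size": len(query),
        "effect": config.enrichment_effect,
    }
    return sets, query, manifest


def write_bundle(config: SimConfig, outdir: str | Path) -> dict:
    """Emit the full synthetic input bundle and a combined manifest.

    Writes compounds.tsv, metabolites.tsv, ppi.tsv, fingerprints.tsv,
    library_fingerprints.tsv, drug_targets.tsv, pathways.gmt, query.txt
    and manifest.json into ``outdir``.  Output is deterministic in
    ``config`` (byte-identical reruns).
    """
    from .adme import write_compound_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    compounds, m_compounds = gen_compound_table(config)
    write_compound_table(compounds, outdir / "compounds.tsv")

    metabolites, m_metabolites = gen_metabolite_table(config)
    with open(outdir / "metabolites.tsv", "w") as handle:
        handle.write(
            "metabolite_id\tparent_id\tparent_name\tscore\treliability\t"
            "reaction_site\treaction_type\tenzyme\n"
        )
        for row in metabolites:
            handle.write(
                f"{row.metabolite_id}\t{row.parent_id}\t{row.parent_name}\t"
                f"{row.score:.6f}\t{row.reliability:.6f}\t"
                f"{row.reaction_site}\t{row.reaction_type}\t{row.enzyme}\n"
            )

    graph, m_ppi = gen_ppi_network(config)
    with open(outdir / "ppi.tsv", "w") as handle:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            handle.write(f"{a}\t{b}\n")

    queries, library, target_map, m_library = gen_drug_library(config)
    write_fingerprints(queries, outdir / "fingerprints.tsv")
    write_fingerprints(library, outdir / "library_fingerprints.tsv")
    write_target_map(target_map, outdir / "drug_targets.tsv")

    gene_sets, query, m_sets = gen_gene_sets(config)
    write_gmt(gene_sets, outdir / "pathways.gmt")
    with open(outdir / "query.txt", "w") as handle:
        for accession in sorted(query):
            handle.write(accession + "\n")

    manifest = {
        "config": asdict(config),
        "compounds": m_compounds,
        "metabolites": m_metabolites,
        "ppi": m_ppi,
        "drug_library": m_library,
        "gene_sets": m_sets,
    }
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return manifest
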