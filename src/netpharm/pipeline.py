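"""End-to-end orchestration of the analysis chain.

annotate → absorption filter → metabolite filter → similarity screening
→ putative-target collection → bipartite network → PPI merge → hub and
major-hub screening → pathway enrichment.  Every stage writes a
line-oriented text output into the run directory and contributes
record-in/record-out counts to a single run report; the report also
carries a hash of the configuration and the seed, so a run is a pure
function of (inputs, config, seed) and can be reproduced byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .adme import (
    filter_absorbed,
    filter_metabolites,
    read_compound_table,
    read_metabolite_table,
    write_compound_table,
)
from .enrichment import enrich, read_gmt
from .network_assembly import build_bipartite, merge_ppi, write_sif
from .synthetic import SimConfig, write_bundle
from .target_prediction import (
    collect_putative_targets,
    read_fingerprints,
    read_target_map,
    screen_similar_drugs,
)
from .topology import identify_hubs, identify_major_hubs, node_topology_table

__all__ = ["PipelineConfig", "run_pipeline", "run_synthetic", "config_hash"]


@dataclass
class PipelineConfig:
    """All thresholds and paths of one pipeline run.

    Thresholds default to the reference study's cutoffs: 5.0 ppm mass
    tolerance, Papp > 7.0 (1e-6 cm/s), metabolite score/reliability >=
    0.6/0.5, similarity > 0.85, hub degree > 2.0 x median.
    """

    tolerance_ppm: float = 5.0
    papp_threshold: float = 7.0
    min_score: float = 0.6
    min_reliability: float = 0.5
    similarity_threshold: float = 0.85
    hub_factor: float = 2.0
    betweenness_variant: str = "normalized"
    closeness_variant: str = "literal"
    radius: int = 1
    seed: int = 0
    outdir: str = "netpharm_run"
    # inputs (paths); any stage whose inputs are None is skipped
    compounds: str | None = None
    metabolites: str | None = None
    fingerprints: str | None = None
    library_fingerprints: str | None = None
    drug_targets: str | None = None
    ppi_edges: list[str] = field(default_factory=list)
    known_targets: str | None = None
    pathways: str | None = None
    enrichment_query: str | None = None

    def __post_init__(self) -> None:
        if self.tolerance_ppm <= 0 or self.papp_threshold <= 0:
            raise ValueError("tolerances must be positive")
        for name in ("min_score", "min_reliability"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [0,1]")
        if not 0.0 <= self.similarity_threshold <= 1.0:
            raise ValueError("similarity_threshold outside [0,1]")
        if self.hub_factor <= 0:
            raise ValueError("hub_factor must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)


_PATH_FIELDS = (
    "outdir", "compounds", "metabolites", "fingerprints",
    "library_fingerprints", "drug_targets", "ppi_edges",
    "known_targets", "pathways", "enrichment_query",
)


def config_hash(config: PipelineConfig) -> str:
    """Stable SHA-256 of the scientific parameters of a configuration.

    Path fields are excluded so that the same analysis relocated to a
    different directory hashes identically; input content is the
    caller's responsibility.
    """
    params = {
        k: v for k, v in config.to_dict().items() if k not in _PATH_FIELDS
    }
    canonical = json.dumps(params, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


class StageError(RuntimeError):
    """A stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages whose inputs are configured; return the run report.

    Stage outputs land in ``config.outdir``; the report (also written as
    report.json) aggregates per-stage input/output counts plus the
    provenance block (config hash, package version, seed).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "config_hash": config_hash(config),
            "netpharm_version": __version__,
            "seed": config.seed,
        },
        "stages": {},
    }
    stages = report["stages"]
    putative_per_compound: dict[str, set[str]] = {}
    putative_targets: set[str] = set()

    if config.compounds:
        try:
            compounds = read_compound_table(config.compounds)
            absorbed = filter_absorbed(compounds, config.papp_threshold)
            write_compound_table(absorbed, outdir / "absorbed.tsv")
            stages["adme_filter"] = {
                "n_input": len(compounds),
                "n_retained": len(absorbed),
                "threshold": config.papp_threshold,
            }
        except Exception as exc:  # noqa: BLE001 - aborts with stage name
            raise StageError("adme_filter", exc) from exc

    if config.metabolites:
        try:
            rows = read_metabolite_table(config.metabolites)
            kept = filter_metabolites(
                rows, config.min_score, config.min_reliability
            )
            with open(outdir / "metabolites_retained.tsv", "w") as handle:
                handle.write("metabolite_id\tn_sites\n")
                for mid, site_rows in kept.items():
                    handle.write(f"{mid}\t{len(site_rows)}\n")
            stages["metabolite_filter"] = {
                "n_input_rows": len(rows),
                "n_retained_metabolites": len(kept),
                "min_score": config.min_score,
                "min_reliability": config.min_reliability,
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("metabolite_filter", exc) from exc

    if config.fingerprints and config.library_fingerprints:
        try:
            queries = read_fingerprints(config.fingerprints)
            library = read_fingerprints(config.library_fingerprints)
            hits = screen_similar_drugs(
                queries, library, config.similarity_threshold
            )
            with open(outdir / "similarity_hits.tsv", "w") as handle:
                handle.write("compound_id\tdrug_id\tscore\n")
                for hit in hits:
                    handle.write(
                        f"{hit.compound_id}\t{hit.drug_id}\t{hit.score:.6f}\n"
                    )
            stages["similarity_screen"] = {
                "n_queries": len(queries),
                "n_library": len(library),
                "n_hits": len(hits),
                "threshold": config.similarity_threshold,
            }
            if config.drug_targets:
                target_map = read_target_map(config.drug_targets)
                collected = collect_putative_targets(hits, target_map)
                putative_targets = collected.targets
                putative_per_compound = collected.per_compound
                with open(outdir / "putative_targets.txt", "w") as handle:
                    for acc in sorted(putative_targets):
                        handle.write(acc + "\n")
                stages["putative_targets"] = {
                    "n_targets": len(putative_targets),
                    "n_missing_drugs": len(collected.missing_drugs),
                }
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("similarity_screen", exc) from exc

    if putative_per_compound:
        try:
            graph, stats = build_bipartite(putative_per_compound)
            write_sif(graph, outdir / "bipartite.sif")
            stages["bipartite_network"] = dataclasses.asdict(stats)
        except Exception as exc:  # noqa: BLE001
            raise StageError("bipartite_network", exc) from exc

    if config.ppi_edges:
        try:
            sources = {
                f"SRC{i + 1}": path
                for i, path in enumerate(config.ppi_edges)
            }
            ppi, merge_report = merge_ppi(sources)
            stages["merge_ppi"] = {
                "n_input_edges": merge_report.n_input_edges,
                "n_edges": ppi.number_of_edges(),
                "n_nodes": ppi.number_of_nodes(),
                "n_self_loops": merge_report.n_self_loops,
                "n_duplicates": merge_report.n_duplicate_edges,
            }
            screen = identify_hubs(ppi, config.hub_factor)
            screen = identify_major_hubs(
                ppi,
                screen,
                betweenness_variant=config.betweenness_variant,
                closeness_variant=config.closeness_variant,
            )
            table = node_topology_table(ppi)
            table["is_hub"] = table.index.isin(screen.hubs)
            table["is_major_hub"] = table.index.isin(screen.major_hubs)
            table.sort_index().to_csv(outdir / "topology.tsv", sep="\t")
            stages["topology"] = {
                "median_degree": screen.median_degree,
                "n_hubs": len(screen.hubs),
                "n_major_hubs": len(screen.major_hubs),
                "thresholds": {
                    k: float(v) for k, v in screen.thresholds.items()
                },
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("topology", exc) from exc

    if config.pathways and (config.enrichment_query or putative_targets):
        try:
            gene_sets = read_gmt(config.pathways)
            if config.enrichment_query:
                with open(config.enrichment_query) as handle:
                    query = {
                        line.strip() for line in handle if line.strip()
                    }
            else:
                query = putative_targets
            results = enrich(query, gene_sets)
            with open(outdir / "enrichment.tsv", "w") as handle:
                handle.write(
                    "pathway_id\tname\tk\tK\tn\tN\tp_value\tadjusted_p\n"
                )
                for r in results:
                    handle.write(
                        f"{r.pathway_id}\t{r.pathway_name}\t{r.k}\t{r.K}\t"
                        f"{r.n}\t{r.N}\t{r.p_value:.6e}\t{r.adjusted_p:.6e}\n"
                    )
            stages["enrichment"] = {
                "n_query": len(query),
                "n_sets_tested": len(results),
                "top_pathway": results[0].pathway_id if results else None,
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("enrichment", exc) from exc

    with open(outdir / "report.json", "w") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return report


def run_synthetic(
    sim: SimConfig, config: PipelineConfig | None = None
) -> dict:
    """Generate a synthetic bundle and run the full pipeline over it."""
    config = config or PipelineConfig()
    outdir = Path(config.outdir)
    bundle = outdir / "bundle"
    write_bundle(sim, bundle)
    config = dataclasses.replace(
        config,
        seed=sim.seed,
        compounds=str(bundle / "compounds.tsv"),
        metabolites=str(bundle / "metabolites.tsv"),
        fingerprints=str(bundle / "fingerprints.tsv"),
        library_fingerprints=str(bundle / "library_fingerprints.tsv"),
        drug_targets=str(bundle / "drug_targets.tsv"),
        ppi_edges=[str(bundle / "ppi.tsv")],
        pathways=str(bundle / "pathways.gmt"),
        enrichment_query=str(bundle / "query.txt"),
        outdir=str(outdir),
    )
    return run_pipeline(config)
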