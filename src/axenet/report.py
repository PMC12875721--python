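"""End-to-end pipeline: master table -> networks -> metrics -> clusters ->
cliques -> success rates -> quality and antibiotic summaries.

The report mirrors the published result layout: one block per analysed
division with overall network statistics, the modularity partition, the
per-cluster statistics and largest cliques, and the per-method success
rates; plus global blocks for the quality-score histogram, antibiotic
summaries and verification-method tallies.  Every convention the pipeline
chose (density convention, edge weighting, exact-search cap, rounding rule)
is echoed in the report so results are auditable, and rerunning on identical
inputs yields a byte-identical JSON serialisation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import antibiotics as ab
from .cliques import largest_cliques_in_cluster
from .clustering import DEFAULT_MAX_EXACT_N, Partition, optimal_partition
from .master_table import DIVISIONS, MasterTable, read_master_table
from .metrics import edge_density, degree_stats, metrics_report, modularity
from .network import (
    build_axenisation_network,
    build_verification_network,
    to_undirected,
)
from .quality import summarize_scores
from .success import division_summary, method_success_rates

logger = logging.getLogger("axenet")


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis conventions; all defaults are recorded in the report."""

    density_convention: str = "directed"   # "directed" (n^2) or "undirected"
    weighted: bool = True                  # weight edges for clustering
    keep_loops: bool = False               # keep self-loops in undirected view
    max_exact_n: int = DEFAULT_MAX_EXACT_N
    divisions: tuple[str, ...] | None = None  # None: every non-empty division
    rounding: str = "half-away-from-zero"  # rubric aggregation rule (fixed)


def _division_block(table: MasterTable, division: str, config: PipelineConfig) -> dict:
    net = build_axenisation_network(table, division)
    directed = net.method_graph()
    und = to_undirected(net, keep_loops=config.keep_loops, weighted=config.weighted)
    partition = optimal_partition(und, max_exact_n=config.max_exact_n)
    cliques = largest_cliques_in_cluster(und, partition)
    overall = metrics_report(
        directed,
        label=f"{division}/overall",
        convention=config.density_convention,
        modularity_q=partition.q,
    )
    clusters = []
    for cid, members in enumerate(partition.communities()):
        sub = directed.subgraph(members)
        _, med = degree_stats(sub, members)
        clusters.append(
            {
                "cluster": cid + 1,
                "nodes": list(members),
                "density": edge_density(sub, members, convention=config.density_convention),
                "median_degree": med,
                "largest_cliques": [list(c.members) for c in cliques.get(cid, [])],
            }
        )
    rates = method_success_rates(table, division)
    return {
        "division": division,
        "n_records": net.n_records,
        "n_publications": len({r.publication_id for r in table.records if r.division == division}),
        "overall": overall.to_dict(),
        "partition": {
            "assignment": dict(sorted(partition.assignment.items())),
            "q": partition.q,
            "method": partition.method,
        },
        "clusters": clusters,
        "success_rates": [
            {
                "method": e.method,
                "n_uses": e.n_uses,
                "n_success": e.n_success,
                "rate": e.rate,
                "below_filter_limit": e.below_filter_limit,
            }
            for e in rates
        ],
    }


@dataclass(frozen=True)
class AnalysisReport:
    config: dict
    divisions: dict
    quality: dict
    antibiotics: dict
    verification: dict
    summary: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls(**json.loads(text))


def run_pipeline(table: MasterTable | str, config: PipelineConfig | None = None) -> AnalysisReport:
    """Execute every analysis stage and assemble the report.

    ``table`` may be a loaded :class:`MasterTable` or a CSV path.  Any stage
    failure is re-raised annotated with the stage name.
    """
    config = config or PipelineConfig()
    stage = "master_table"
    try:
        if not isinstance(table, MasterTable):
            table = read_master_table(table)
        logger.info("master_table: %d records, %d publications", len(table), len(table.publication_ids))

        stage = "networks"
        wanted = config.divisions or tuple(
            d for d in DIVISIONS if any(r.division == d for r in table.records)
        )
        blocks = {}
        for div in wanted:
            stage = f"division:{div}"
            blocks[div] = _division_block(table, div, config)
            logger.info(
                "%s: %d nodes, Q=%.3f, %d clusters",
                div,
                blocks[div]["overall"]["n_nodes"],
                blocks[div]["partition"]["q"],
                len(blocks[div]["clusters"]),
            )

        stage = "quality"
        quality = summarize_scores(table)

        stage = "antibiotics"
        uses = ab.collect_uses(table)
        compound_freq = ab.compound_frequency(uses)
        pairs, class_pairs = ab.cocktail_combinations(uses)
        class_summary = ab.class_concentration_summary(uses)

        stage = "verification"
        ver = build_verification_network(table)

        stage = "summary"
        summaries = division_summary(table)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return AnalysisReport(
        config={
            "density_convention": config.density_convention,
            "weighted": config.weighted,
            "keep_loops": config.keep_loops,
            "max_exact_n": config.max_exact_n,
            "rounding": config.rounding,
        },
        divisions=blocks,
        quality={
            "histogram": {str(k): v for k, v in quality.histogram.items()},
            "by_period": {p: {str(k): v for k, v in h.items()} for p, h in quality.by_period.items()},
            "n_publications": quality.n_publications,
            "n_below_zero": quality.n_below_zero,
        },
        antibiotics={
            "n_publications_with_antibiotics": ab.n_publications_with_antibiotics(table),
            "class_summary": {
                cls: {div: asdict(cell) for div, cell in sorted(cells.items())}
                for cls, cells in sorted(class_summary.items())
            },
            "compound_frequency": compound_freq.to_dict(orient="records"),
            "compound_pairs": {" + ".join(k): v for k, v in sorted(pairs.items())},
            "class_pairs": {" + ".join(k): v for k, v in sorted(class_pairs.items())},
        },
        verification={
            "usage": dict(ver.usage),
            "group_totals": dict(ver.group_totals),
            "edges": {f"{u} + {v}": int(d["weight"]) for u, v, d in sorted(ver.graph.edges(data=True))},
        },
        summary={
            div: {
                "n_publications": s.n_publications,
                "n_species": s.n_species,
                "method_type_counts": s.method_type_counts,
                "n_genera": s.n_genera,
                "outcome_tally": s.outcome_tally,
            }
            for div, s in summaries.items()
        },
    )


def network_table(report: AnalysisReport) -> pd.DataFrame:
    """Flat per-(division, cluster) table of the network statistics,
    mirroring the published summary layout (Overall row first)."""
    rows = []
    for div, block in report.divisions.items():
        overall = block["overall"]
        rows.append(
            {
                "division": div,
                "cluster": "Overall",
                "nodes": ", ".join(sorted(block["partition"]["assignment"])),
                "density": round(overall["density"], 2),
                "median_degree": overall["median_degree"],
                "modularity_q": round(block["partition"]["q"], 3),
            }
        )
        for cl in block["clusters"]:
            rows.append(
                {
                    "division": div,
                    "cluster": f"Cluster {cl['cluster']}",
                    "nodes": ", ".join(cl["nodes"]),
                    "density": round(cl["density"], 2),
                    "median_degree": cl["median_degree"],
                    "modularity_q": None,
                    "cliques": "; ".join(", ".join(c) for c in cl["largest_cliques"]),
                }
            )
    return pd.DataFrame(rows)
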