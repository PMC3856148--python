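"""Disease-subnetwork extraction and node centralities.

The disease-associated subnetwork is the induced subgraph on the top
fraction (default 3%) of nodes by disease propagation score.  On it we
compute the three classic centralities — degree, betweenness (normalised by
(n-1)(n-2)/2 over unordered pairs), and k-core coreness — and annotate each
node with disease-gene membership and the formula components targeting it.
Centralities are computed on the unweighted simple-graph view: edge weights
drive the random walk, not the shortest-path or peeling definitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .netio import DrugTargetTable, WeightedNetwork
from .propagate import PropagationResult

__all__ = [
    "Subnetwork",
    "TopologyReport",
    "extract_top_fraction",
    "degrees",
    "kcore_decomposition",
    "betweenness_centrality",
    "annotate_targets",
]

DEFAULT_TOP_FRACTION = 0.03


@dataclass(frozen=True)
class Subnetwork:
    """Induced subgraph on the selected high-scoring nodes.

    ``graph`` is a plain :class:`networkx.Graph`: unlike the parent
    interactome it may legitimately contain isolated members.  Disease-gene
    coverage (how many disease genes the selection retains) is filled when
    the caller passes the disease gene set at extraction time.
    """

    graph: nx.Graph
    members: tuple[str, ...]
    selection_fraction: float
    scores: Mapping[str, float]
    disease_genes_retained: int | None = None
    disease_genes_total: int | None = None

    @property
    def disease_gene_coverage_pct(self) -> float | None:
        if self.disease_genes_total in (None, 0):
            return None
        return 100.0 * self.disease_genes_retained / self.disease_genes_total

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class TopologyReport:
    """Per-node centrality table plus target-location summary.

    ``table`` columns: gene, degree, betweenness, k_coreness,
    is_disease_gene, targeted_by (semicolon-joined component/drug ids).
    ``summary`` reports, over nodes that are drug/component targets, the
    fraction with degree above the subnetwork mean, betweenness above the
    mean, and coreness equal to the maximum coreness; each is None when no
    target lies on the subnetwork.
    """

    table: pd.DataFrame
    summary: dict

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def extract_top_fraction(
    network: WeightedNetwork,
    scores: PropagationResult,
    fraction: float = DEFAULT_TOP_FRACTION,
    disease_genes: Iterable[str] | None = None,
    drop_zero_scores: bool = False,
) -> Subnetwork:
    """Induced subgraph on the floor(fraction * |nodes|) highest-scoring nodes.

    Ordering is by score descending with lexicographic symbol tie-break, so
    the selection is deterministic.  ``drop_zero_scores`` excludes
    zero-score nodes before counting (an option for walks whose mass never
    reaches some components).
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    missing = [v for v in network.node_order if v not in scores.scores]
    if missing:
        raise ValueError(f"scores missing for {len(missing)} network nodes")
    pool = list(network.node_order)
    if drop_zero_scores:
        pool = [v for v in pool if scores.scores[v] > 0.0]
    k = math.floor(fraction * network.number_of_nodes())
    if k < 1:
        raise ValueError(
            f"fraction {fraction} selects no nodes from "
            f"{network.number_of_nodes()}"
        )
    ranked = sorted(pool, key=lambda v: (-scores.scores[v], v))
    members = tuple(sorted(ranked[:k]))
    sub = network.subgraph(members)

    retained = total = None
    if disease_genes is not None:
        dg = {g.strip().upper() for g in disease_genes}
        total = len(dg)
        retained = len(dg & set(members))
    return Subnetwork(
        graph=sub,
        members=members,
        selection_fraction=fraction,
        scores={v: scores.scores[v] for v in members},
        disease_genes_retained=retained,
        disease_genes_total=total,
    )


def degrees(subnetwork: Subnetwork | nx.Graph) -> dict[str, int]:
    """Simple-graph degree of every node."""
    g = subnetwork.graph if isinstance(subnetwork, Subnetwork) else subnetwork
    return dict(g.degree())


def kcore_decomposition(subnetwork: Subnetwork | nx.Graph) -> dict[str, int]:
    """Coreness: the largest k at which a node survives recursive deletion
    of all nodes with current degree < k."""
    g = subnetwork.graph if isinstance(subnetwork, Subnetwork) else subnetwork
    return dict(nx.core_number(g))


def betweenness_centrality(
    subnetwork: Subnetwork | nx.Graph, normalized: bool = True
) -> dict[str, float]:
    """Exact shortest-path betweenness on the unweighted graph.

    Unordered source-target pairs; normalisation divides by
    (n-1)(n-2)/2.  Pairs in different components contribute nothing.
    """
    g = subnetwork.graph if isinstance(subnetwork, Subnetwork) else subnetwork
    return dict(nx.betweenness_centrality(g, normalized=normalized))


def annotate_targets(
    subnetwork: Subnetwork,
    disease_genes: Iterable[str],
    drug_table: DrugTargetTable,
) -> TopologyReport:
    """Join centralities with disease-gene and drug-target annotations.

    ``targeted_by`` lists the drugs/components targeting each node.  Summary
    fractions compare target nodes against the subnetwork-wide mean degree,
    mean betweenness, and maximum coreness; they are None when no target is
    on the subnetwork.
    """
    dg = {g.strip().upper() for g in disease_genes}
    targeting: dict[str, list[str]] = {}
    for rec in drug_table.records:
        targeting.setdefault(rec.target, []).append(rec.drug_id)

    deg = degrees(subnetwork)
    btw = betweenness_centrality(subnetwork)
    core = kcore_decomposition(subnetwork)

    rows = []
    for v in subnetwork.members:
        rows.append(
            {
                "gene": v,
                "degree": deg[v],
                "betweenness": btw[v],
                "k_coreness": core[v],
                "is_disease_gene": v in dg,
                "targeted_by": ";".join(sorted(set(targeting.get(v, [])))),
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["degree", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)

    n_nodes = subnetwork.number_of_nodes()
    mean_deg = sum(deg.values()) / n_nodes
    mean_btw = sum(btw.values()) / n_nodes
    max_core = max(core.values()) if core else 0
    on_net_targets = [v for v in subnetwork.members if v in targeting]

    if on_net_targets:
        nt = len(on_net_targets)
        summary = {
            "n_targets_on_subnetwork": nt,
            "mean_degree": mean_deg,
            "mean_betweenness": mean_btw,
            "max_coreness": max_core,
            "frac_targets_degree_above_mean": sum(
                deg[v] > mean_deg for v in on_net_targets
            ) / nt,
            "frac_targets_betweenness_above_mean": sum(
                btw[v] > mean_btw for v in on_net_targets
            ) / nt,
            "frac_targets_in_max_core": sum(
                core[v] == max_core for v in on_net_targets
            ) / nt,
        }
    else:
        summary = {
            "n_targets_on_subnetwork": 0,
            "mean_degree": mean_deg,
            "mean_betweenness": mean_btw,
            "max_coreness": max_core,
            "frac_targets_degree_above_mean": None,
            "frac_targets_betweenness_above_mean": None,
            "frac_targets_in_max_core": None,
        }
    return TopologyReport(table=table, summary=summary)
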