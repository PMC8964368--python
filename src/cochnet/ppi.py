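"""Module-induced PPI subnetworks, centralities, hubs and coverage.

The protein-protein interaction network arrives as a STRING-style edge list
(protein1, protein2, combined_score in 0-999).  For a module's gene list the
induced subnetwork is analysed with two node centralities — degree and
closeness (normalised within each connected component, so it is well-defined
on disconnected induced graphs; isolated nodes get 0) — hubs are the top-k
nodes by degree (closeness, then gene id, break ties), and the hub report
quantifies how much of the module the hubs reach: the fraction of input
genes directly adjacent to a hub and the fraction of subnetwork edges
incident to a hub.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import ConfigError, ParseError, ValidationError


def read_edge_list(path: str | Path, score_threshold: int = 400) -> nx.Graph:
    """Read a STRING-style TSV keeping edges with score >= threshold.

    Self-loops are dropped; duplicate unordered pairs collapse to one edge
    (the first score read wins).
    """
    df = pd.read_csv(path, sep="\t")
    needed = {"protein1", "protein2", "combined_score"}
    if not needed <= set(df.columns):
        raise ParseError(f"edge list must have columns {sorted(needed)}")
    if not pd.api.types.is_integer_dtype(df["combined_score"]):
        raise ParseError("combined_score must be integer")
    g = nx.Graph()
    dropped_loops = 0
    for u, v, s in df.itertuples(index=False):
        if u == v:
            dropped_loops += 1
            continue
        if s < score_threshold:
            continue
        if not g.has_edge(u, v):
            g.add_edge(u, v, combined_score=int(s))
    g.graph["dropped_self_loops"] = dropped_loops
    return g


def induce_subnetwork(g: nx.Graph, gene_list) -> tuple[nx.Graph, list[str]]:
    """Subgraph on ``gene_list``; returns (subgraph, genes absent from g).

    Absent genes still count in coverage denominators downstream, so they
    are reported rather than silently discarded.  Genes in the list but
    isolated in the subnetwork keep their node (degree 0).
    """
    genes = list(dict.fromkeys(gene_list))  # dedupe, preserve order
    if not genes:
        raise ValidationError("gene list is empty")
    present = [x for x in genes if g.has_node(x)]
    missing = [x for x in genes if not g.has_node(x)]
    if not present:
        warnings.warn("no gene of the list is present in the network",
                      stacklevel=2)
    sub = nx.Graph(g.subgraph(present))
    return sub, missing


def degree_centrality(g: nx.Graph) -> pd.Series:
    """Raw degree (incident edge count) per node."""
    return pd.Series(dict(g.degree()), dtype=int).sort_index()


def closeness_centrality(g: nx.Graph) -> pd.Series:
    """Closeness Cc(i) = (n_c - 1) / sum_j d(i, j) within i's component.

    Unweighted shortest paths; isolated nodes get 0.
    """
    cc = nx.closeness_centrality(g, wf_improved=False)
    return pd.Series(cc, dtype=float).sort_index()


def centrality_table(g: nx.Graph) -> pd.DataFrame:
    deg = degree_centrality(g)
    clo = closeness_centrality(g)
    return pd.DataFrame({"gene": deg.index, "degree": deg.to_numpy(),
                         "closeness": clo.loc[deg.index].to_numpy()})


def select_hubs(table: pd.DataFrame, k: int = 15) -> list[str]:
    """Top-k genes by degree; ties by closeness, then lexical gene id."""
    if k <= 0:
        raise ConfigError("hub count k must be positive")
    if table.empty:
        raise ValidationError("centrality table is empty")
    ranked = table.sort_values(
        by=["degree", "closeness", "gene"], ascending=[False, False, True],
        kind="stable",
    )
    return ranked["gene"].head(k).tolist()


@dataclass
class HubReport:
    hubs: list[str]
    covered_genes: int
    gene_total: int
    gene_coverage: float  # fraction of the input list adjacent to >= 1 hub
    covered_edges: int
    edge_total: int
    edge_coverage: float  # fraction of edges incident to >= 1 hub

    def to_dict(self) -> dict:
        return {
            "hubs": list(self.hubs),
            "covered_genes": self.covered_genes,
            "gene_total": self.gene_total,
            "gene_coverage": self.gene_coverage,
            "covered_edges": self.covered_edges,
            "edge_total": self.edge_total,
            "edge_coverage": self.edge_coverage,
        }


def hub_coverage(g: nx.Graph, hubs, input_gene_list) -> HubReport:
    """How much of the module the hub set reaches directly.

    gene-coverage counts non-hub genes of the (deduplicated) input list that
    are adjacent to at least one hub, over the full input list (including
    genes absent from the graph); edge-coverage counts edges of ``g`` with a
    hub endpoint, over all edges of ``g``.
    """
    genes = list(dict.fromkeys(input_gene_list))
    if not genes:
        raise ValidationError("input gene list is empty")
    hub_set = set(hubs)
    if not hub_set <= set(g.nodes):
        raise ValidationError("hubs must be nodes of the graph")
    covered = sum(
        1
        for x in genes
        if x not in hub_set
        and g.has_node(x)
        and any(nb in hub_set for nb in g.neighbors(x))
    )
    edge_total = g.number_of_edges()
    covered_edges = sum(
        1 for u, v in g.edges() if u in hub_set or v in hub_set
    )
    return HubReport(
        hubs=list(hubs),
        covered_genes=covered,
        gene_total=len(genes),
        gene_coverage=covered / len(genes),
        covered_edges=covered_edges,
        edge_total=edge_total,
        edge_coverage=(covered_edges / edge_total) if edge_total else 0.0,
    )


def module_hub_analysis(
    g: nx.Graph, gene_list, k: int = 15
) -> tuple[pd.DataFrame, HubReport, list[str]]:
    """Induce, rank, select hubs and compute coverage for one module list."""
    sub, missing = induce_subnetwork(g, gene_list)
    if sub.number_of_nodes() == 0:
        raise ValidationError("no module gene is present in the PPI network")
    table = centrality_table(sub)
    hubs = select_hubs(table, k=k)
    report = hub_coverage(sub, hubs, gene_list)
    return table, report, missing
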