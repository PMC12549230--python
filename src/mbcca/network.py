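"""Spearman association networks, community structure, centralities, hubs.

Within one experimental group, all pairs of differential features (host
genes, microbial taxa, microbial genes) are tested by Spearman
correlation; pairs with p < p_max and rho >= rho_min (or |rho| >= rho_min
in absolute mode) become edges weighted by -log10(p). Communities come
from greedy modularity maximization; per-node records carry degree,
unnormalized shortest-path betweenness, and neighborhood connectivity
(mean degree of neighbors). Hubs are nodes of high neighborhood
connectivity among adequately connected nodes. A dedicated extractor
tabulates associations between a flagged microbial gene family (e.g.
aminoacyl-tRNA synthetases) and host genes grouped by small GO terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .datamodel import FeatureTable, ValidationError

log = logging.getLogger("mbcca")


def spearman_edges(
    table: FeatureTable,
    p_max: float = 0.05,
    rho_min: float = 0.5,
    mode: str = "signed",
) -> pd.DataFrame:
    """All-pairs Spearman correlations filtered to network edges.

    Spearman rho uses average ranks for ties; p-values come from the
    t-distribution approximation. ``mode="signed"`` keeps pairs with
    rho >= rho_min; ``mode="absolute"`` keeps |rho| >= rho_min. Constant
    features are skipped with a logged warning. Edge weight is -log10(p).
    """
    if mode not in ("signed", "absolute"):
        raise ValidationError("mode must be 'signed' or 'absolute'")
    if table.n_samples < 4:
        raise ValidationError("Spearman networks need at least 4 samples")
    if table.n_features < 2:
        raise ValidationError("need at least two features")
    variances = table.values.std(axis=0)
    constant = [f for f, s in zip(table.feature_ids, variances) if s == 0]
    if constant:
        log.warning("skipping %d constant features: %s",
                    len(constant), constant[:10])
    keep = [f for f in table.feature_ids if f not in set(constant)]
    if len(keep) < 2:
        raise ValidationError("fewer than two non-constant features")
    sub = table.data[keep]
    rho, p = spearmanr(sub.to_numpy())
    if np.ndim(rho) == 0:  # spearmanr returns scalars for two features
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    rows = []
    m = len(keep)
    for i in range(m):
        for j in range(i + 1, m):
            r = float(rho[i, j])
            pv = float(p[i, j])
            passes = r >= rho_min if mode == "signed" else abs(r) >= rho_min
            if passes and pv < p_max:
                weight = float(-np.log10(max(pv, 1e-300)))
                rows.append((keep[i], keep[j], r, pv, weight))
    return pd.DataFrame(
        rows, columns=["source", "target", "rho", "p", "weight"]
    )


@dataclass
class AssociationNetwork:
    """Undirected simple association graph with global properties."""

    graph: nx.Graph
    properties: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    edges: pd.DataFrame, node_meta: pd.DataFrame | None = None
) -> AssociationNetwork:
    """Assemble an association network from a filtered edge table.

    ``node_meta`` (indexed by node id) may carry ``layer`` (host_gene /
    microbial_taxon / microbial_gene), ``taxon``, ``is_aaRS``, etc.
    Global properties: node/edge counts, density 2E/(N(N-1)), and the
    average number of neighbors (mean degree). Contradictory duplicate
    edges (same pair, different rho) raise.
    """
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        a, b = row.source, row.target
        if a == b:
            raise ValidationError(f"self-loop on {a!r}")
        if g.has_edge(a, b) and not np.isclose(g[a][b]["rho"], row.rho):
            raise ValidationError(f"contradictory duplicate edge {a!r}-{b!r}")
        g.add_edge(a, b, rho=float(row.rho), p=float(row.p),
                   weight=float(row.weight))
    if node_meta is not None:
        for node in g.nodes:
            if node in node_meta.index:
                for key, val in node_meta.loc[node].items():
                    if pd.notna(val):
                        g.nodes[node][key] = val
    n, e = g.number_of_nodes(), g.number_of_edges()
    density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
    avg_neighbors = 2.0 * e / n if n else 0.0
    props = {
        "n_nodes": n,
        "n_edges": e,
        "density": density,
        "average_neighbors": avg_neighbors,
    }
    return AssociationNetwork(g, props)


def community_clusters(
    net: AssociationNetwork, seed: int = 0
) -> tuple[dict, float]:
    """Community detection by greedy modularity maximization.

    Returns (node -> cluster label, modularity Q of the partition).
    Isolated nodes each form their own cluster. The greedy algorithm is
    deterministic; ``seed`` is accepted for interface uniformity.
    """
    g = net.graph
    if g.number_of_edges() < 1:
        raise ValidationError("community detection needs at least one edge")
    communities = nx.community.greedy_modularity_communities(g)
    labels = {}
    for ci, nodes in enumerate(communities):
        for node in nodes:
            labels[node] = ci
    q = nx.community.modularity(g, communities)
    return labels, float(q)


@dataclass
class CentralityRecord:
    """Degree, betweenness, and neighborhood connectivity of one node."""

    node: str
    degree: int
    betweenness: float
    neighborhood_connectivity: float


def centrality_metrics(net: AssociationNetwork) -> pd.DataFrame:
    """Per-node degree, betweenness, and neighborhood connectivity.

    Betweenness is unnormalized shortest-path betweenness with each
    unordered pair counted once. Neighborhood connectivity is the mean
    degree of a node's neighbors (0 for isolated nodes).
    """
    g = net.graph
    betweenness = nx.betweenness_centrality(g, normalized=False)
    rows = []
    for node in g.nodes:
        neighbors = list(g.neighbors(node))
        nc = float(np.mean([g.degree(x) for x in neighbors])) if neighbors else 0.0
        rows.append((str(node), g.degree(node), float(betweenness[node]), nc))
    return pd.DataFrame(
        rows,
        columns=["node", "degree", "betweenness", "neighborhood_connectivity"],
    )


@dataclass
class HubReport:
    """Ranked centrality table with hub flags."""

    table: pd.DataFrame  # sorted by descending NC, ties by node id
    quantile: float
    min_degree: int

    def to_frame(self) -> pd.DataFrame:
        return self.table.reset_index(drop=True)

    def hub_ids(self) -> list[str]:
        return self.table.loc[self.table["hub"], "node"].tolist()


def identify_hubs(
    records: pd.DataFrame,
    quantile: float = 0.90,
    min_degree: int = 2,
    clusters: dict | None = None,
) -> HubReport:
    """Flag hub nodes by high neighborhood connectivity.

    Eligible nodes have degree >= min_degree; hubs are eligible nodes
    whose neighborhood connectivity reaches the given quantile among
    eligible nodes (boundary ties included). The report ranks all nodes
    by descending neighborhood connectivity, ties broken by node id.
    """
    if records.empty:
        raise ValidationError("no centrality records")
    df = records.copy()
    eligible = df["degree"] >= min_degree
    if eligible.any():
        cutoff = float(
            np.quantile(df.loc[eligible, "neighborhood_connectivity"], quantile)
        )
        df["hub"] = eligible & (df["neighborhood_connectivity"] >= cutoff)
    else:
        df["hub"] = False
    if clusters is not None:
        df["cluster"] = df["node"].map(clusters)
    df = df.sort_values(
        ["neighborhood_connectivity", "node"], ascending=[False, True]
    ).reset_index(drop=True)
    return HubReport(df, quantile, min_degree)


def extract_gene_family_associations(
    net: AssociationNetwork,
    go_annotation: pd.DataFrame,
    family_flag: str = "is_aaRS",
    max_term_size: int = 100,
) -> pd.DataFrame:
    """Tabulate flagged-gene-family <-> host-gene associations by GO term.

    Restricts to edges joining a node flagged ``family_flag`` (e.g. a
    microbial aminoacyl-tRNA synthetase gene) to a host gene, groups the
    host genes by their GO annotation, and drops terms annotating
    ``max_term_size`` or more genes. Output rows are
    (microbe, go_term, n_host_genes, mean_rho) — the chord-diagram input.
    """
    if go_annotation is None:
        raise ValidationError("a gene -> GO-term annotation table is required")
    g = net.graph
    term_sizes = go_annotation.groupby("go_term")["gene"].nunique()
    small_terms = set(term_sizes[term_sizes < max_term_size].index)
    gene_terms = (
        go_annotation[go_annotation["go_term"].isin(small_terms)]
        .groupby("gene")["go_term"]
        .apply(list)
        .to_dict()
    )
    rows = []
    for a, b, attrs in g.edges(data=True):
        for fam_node, host_node in ((a, b), (b, a)):
            if not g.nodes[fam_node].get(family_flag, False):
                continue
            if g.nodes[host_node].get("layer") != "host_gene":
                continue
            microbe = g.nodes[fam_node].get("taxon", "unknown")
            for term in gene_terms.get(host_node, []):
                rows.append((microbe, term, host_node, attrs["rho"]))
    if not rows:
        return pd.DataFrame(
            columns=["microbe", "go_term", "n_host_genes", "mean_rho"]
        )
    df = pd.DataFrame(rows, columns=["microbe", "go_term", "gene", "rho"])
    out = (
        df.groupby(["microbe", "go_term"])
        .agg(n_host_genes=("gene", "nunique"), mean_rho=("rho", "mean"))
        .reset_index()
        .sort_values(["microbe", "go_term"])
        .reset_index(drop=True)
    )
    return out
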