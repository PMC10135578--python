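"""The bipartite gene-disease network (diseasome) and its summaries.

Genes and diseases form the two sides of a bipartite graph whose edges are
unique gene-disease associations.  This module builds the graph, computes
the two degree tables (genes per disease, diseases per gene), extracts the
collagen sub-diseasome, clusters genes by the similarity of their disease
neighbor sets, and screens protein-protein interaction pairs for
matrisome-matrisome edges.

Node identity is the normalized name, typed by side: internal node keys are
``"gene::SYMBOL"`` and ``"disease::name"`` so the same string can never occur
on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .records import Category, GeneDiseaseAssociation, MatrisomeCatalog, PpiPair

GENE_PREFIX = "gene::"
DISEASE_PREFIX = "disease::"


def _gene_node(symbol: str) -> str:
    return GENE_PREFIX + symbol


def _disease_node(name: str) -> str:
    return DISEASE_PREFIX + name


@dataclass(slots=True)
class BuildReport:
    associations_in: int = 0
    edges: int = 0
    duplicates: int = 0
    rejected: int = 0


def build_bipartite(associations: Iterable[GeneDiseaseAssociation]) -> tuple[nx.Graph, BuildReport]:
    """Build the diseasome graph; duplicated pairs collapse (idempotent).

    A record whose gene symbol equals its disease name is self-contradictory
    and is rejected and counted.
    """
    graph = nx.Graph()
    report = BuildReport()
    for assoc in associations:
        report.associations_in += 1
        if assoc.gene_symbol == assoc.disease:
            report.rejected += 1
            continue
        u, v = _gene_node(assoc.gene_symbol), _disease_node(assoc.disease)
        if graph.has_edge(u, v):
            report.duplicates += 1
            continue
        graph.add_node(u, kind="gene", name=assoc.gene_symbol, bipartite=0)
        graph.add_node(v, kind="disease", name=assoc.disease, bipartite=1)
        graph.add_edge(u, v, source=assoc.source.value)
    report.edges = graph.number_of_edges()
    return graph, report


def gene_nodes(graph: nx.Graph) -> list[str]:
    return sorted(n for n, d in graph.nodes(data=True) if d.get("kind") == "gene")


def disease_nodes(graph: nx.Graph) -> list[str]:
    return sorted(n for n, d in graph.nodes(data=True) if d.get("kind") == "disease")


def _degree_table(graph: nx.Graph, nodes: list[str], label: str) -> pd.DataFrame:
    rows = sorted(((graph.nodes[n]["name"], graph.degree(n)) for n in nodes),
                  key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=[label, "degree"])


def genes_per_disease(graph: nx.Graph) -> pd.DataFrame:
    """Diseases ranked by the number of associated genes (descending)."""
    return _degree_table(graph, disease_nodes(graph), "disease")


def diseases_per_gene(graph: nx.Graph) -> pd.DataFrame:
    """Genes ranked by the number of associated diseases (descending)."""
    return _degree_table(graph, gene_nodes(graph), "gene")


def collagen_subnetwork(graph: nx.Graph, catalog: MatrisomeCatalog) -> nx.Graph:
    """Restrict the diseasome to collagen-category genes and their diseases.

    Diseases left with no surviving edge are dropped, so the operation is
    idempotent.
    """
    collagens = catalog.in_category(Category.COLLAGENS)
    keep_genes = [n for n in gene_nodes(graph) if graph.nodes[n]["name"] in collagens]
    sub = graph.subgraph(
        keep_genes + [d for g in keep_genes for d in graph.neighbors(g)]).copy()
    sub.remove_nodes_from([n for n in list(sub) if sub.degree(n) == 0])
    return sub


def neighbor_sets(graph: nx.Graph) -> dict[str, frozenset[str]]:
    """Disease neighbor set per gene, keyed by gene name, in canonical order."""
    return {graph.nodes[g]["name"]: frozenset(graph.nodes[d]["name"]
                                              for d in graph.neighbors(g))
            for g in gene_nodes(graph)}


def jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    union = len(a | b)
    return len(a & b) / union


def shared_disease_clusters(graph: nx.Graph, cut: float = 0.5,
                            method: str = "average") -> dict[str, int]:
    """Cluster genes by Jaccard similarity of their disease neighbor sets.

    Agglomerative clustering (``scipy`` linkage, ``method`` default average)
    on Jaccard *distance* (1 - similarity); the tree is cut so that clusters
    merge while their linkage distance is at most ``1 - cut``.  Genes with
    identical disease sets co-cluster at any cut < 1; genes with disjoint
    sets separate at any cut > 0.  Deterministic: genes are processed in
    sorted order.  Returns gene -> cluster id (1-based, ids ordered by first
    gene appearance).
    """
    if not (0.0 < cut < 1.0):
        raise ValueError("cut must lie strictly between 0 and 1")
    sets = neighbor_sets(graph)
    if not sets:
        raise ValueError("graph has no gene nodes to cluster")
    genes = sorted(sets)
    if len(genes) == 1:
        return {genes[0]: 1}
    n = len(genes)
    dist = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d = 1.0 - jaccard(sets[genes[i]], sets[genes[j]])
        dist[i, j] = dist[j, i] = d
    labels = fcluster(linkage(squareform(dist, checks=False), method=method),
                      t=1.0 - cut, criterion="distance")
    # Renumber cluster ids by first appearance for reproducible output.
    remap: dict[int, int] = {}
    out: dict[str, int] = {}
    for gene, raw in zip(genes, labels):
        out[gene] = remap.setdefault(int(raw), len(remap) + 1)
    return out


def brute_force_clusters(graph: nx.Graph, cut: float = 0.5) -> dict[str, int]:
    """Independent oracle: threshold pairwise Jaccard, take connected components.

    Two genes are linked when the Jaccard similarity of their disease sets is
    at least ``cut``; clusters are the connected components.  Intended for
    cross-checking :func:`shared_disease_clusters` on small, well-separated
    instances.
    """
    sets = neighbor_sets(graph)
    genes = sorted(sets)
    sim_graph = nx.Graph()
    sim_graph.add_nodes_from(genes)
    for a, b in combinations(genes, 2):
        if jaccard(sets[a], sets[b]) >= cut:
            sim_graph.add_edge(a, b)
    out: dict[str, int] = {}
    next_id = 1
    for gene in genes:
        if gene in out:
            continue
        for member in nx.node_connected_component(sim_graph, gene):
            out[member] = next_id
        next_id += 1
    return out


@dataclass(slots=True)
class PpiScreenResult:
    pairs: list[PpiPair]
    unique_genes: set[str]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_genes(self) -> int:
        return len(self.unique_genes)


def matrisome_ppi_pairs(pairs: Iterable[PpiPair], catalog: MatrisomeCatalog) -> PpiScreenResult:
    """Keep pairs whose both endpoints are matrisome genes."""
    surviving = [p for p in pairs
                 if p.gene_a in catalog and p.gene_b in catalog]
    genes = {g for p in surviving for g in (p.gene_a, p.gene_b)}
    return PpiScreenResult(pairs=surviving, unique_genes=genes)


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def write_edge_list(graph: nx.Graph, path) -> None:
    """Edge-list TSV (gene, disease, source), sorted for reproducibility."""
    rows = sorted(
        (graph.nodes[u]["name"] if graph.nodes[u]["kind"] == "gene" else graph.nodes[v]["name"],
         graph.nodes[v]["name"] if graph.nodes[u]["kind"] == "gene" else graph.nodes[u]["name"],
         data.get("source", ""))
        for u, v, data in graph.edges(data=True))
    pd.DataFrame(rows, columns=["gene", "disease", "source"]).to_csv(
        path, sep="\t", index=False)
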