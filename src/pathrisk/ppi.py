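"""Protein–protein interaction graph: union loading, degrees, DEG subnetwork.

Edge lists (two-column TSV, the usual BioGrid/HPRD tab-export shape) are
merged into one undirected simple graph over upper-cased gene symbols.  The
degree of a gene in this full union graph is the weight ω used by the
functional-deviation score; the induced DEG subnetwork is reported
separately.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx

logger = logging.getLogger(__name__)

_HEADER_TOKENS = {
    "gene", "gene_a", "gene_b", "genea", "geneb", "symbol", "symbol_a",
    "symbol_b", "protein", "protein_a", "protein_b", "interactor",
    "interactor_a", "interactor_b", "node", "node1", "node2", "source",
    "target", "from", "to", "official_symbol",
}


def load_union(edge_files) -> nx.Graph:
    """Merge edge-list files into one undirected simple graph.

    Duplicate edges within and across files collapse (A–B ≡ B–A); self-loops
    are dropped and counted in ``graph.graph["n_self_loops"]``.  A first line
    whose fields look like column names is treated as a header.  Any other
    line without exactly two non-empty fields raises with the file and line
    number.
    """
    graph = nx.Graph()
    n_self = 0
    for path in edge_files:
        path = Path(path)
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                fields = [f.strip() for f in line.rstrip("\n").split("\t")]
                if len(fields) != 2 or not all(fields):
                    raise ValueError(
                        f"{path}:{lineno}: expected two tab-separated symbols, "
                        f"got {line.rstrip()!r}"
                    )
                if lineno == 1 and any(f.lower() in _HEADER_TOKENS for f in fields):
                    continue
                a, b = fields[0].upper(), fields[1].upper()
                if a == b:
                    n_self += 1
                    continue
                graph.add_edge(a, b)
    graph.graph["n_self_loops"] = n_self
    logger.info(
        "union PPI: %d nodes, %d edges (%d self-loops dropped)",
        graph.number_of_nodes(), graph.number_of_edges(), n_self,
    )
    return graph


def deg_subnetwork(graph: nx.Graph, up_degs, down_degs) -> tuple[nx.Graph, dict]:
    """Induced subgraph on DEG nodes, without isolated DEGs.

    Returns the subgraph and a node→direction ("up"/"down") tag map.  Genes
    in both input lists are tagged by the up list (first wins).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("interaction graph is empty")
    direction = {}
    for g in up_degs:
        direction[str(g).upper()] = "up"
    for g in down_degs:
        direction.setdefault(str(g).upper(), "down")
    nodes = [n for n in direction if n in graph]
    sub = graph.subgraph(nodes).copy()
    sub.remove_nodes_from([n for n, d in sub.degree() if d == 0])
    if sub.number_of_nodes() == 0:
        logger.warning("DEG subnetwork is empty (no DEG-DEG interaction)")
    tags = {n: direction[n] for n in sub.nodes}
    return sub, tags


def weight_lookup(graph: nx.Graph, gene: str) -> int:
    """ω(gene): degree in the full union graph; 0 for genes absent from it."""
    gene = str(gene).upper()
    return int(graph.degree(gene)) if gene in graph else 0


def degree_weights(graph: nx.Graph, genes) -> dict[str, int]:
    """Vector of ω over ``genes``."""
    return {g: weight_lookup(graph, g) for g in genes}


def write_node_table(sub: nx.Graph, tags: dict, full_graph: nx.Graph, path) -> None:
    """TSV of subnetwork nodes: gene, direction, full-graph and subnetwork degree."""
    with open(path, "w") as fh:
        fh.write("gene\tdirection\tdegree_full\tdegree_subnetwork\n")
        for n in sorted(sub.nodes):
            fh.write(f"{n}\t{tags[n]}\t{weight_lookup(full_graph, n)}\t{sub.degree(n)}\n")
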