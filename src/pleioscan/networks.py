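"""Variant-gene bipartite networks and disease-gene summaries.

The bipartite network connects each pleiotropic variant to its target
genes; compressing every variant of one disease into a single disease
node yields a weighted disease-gene network whose shared genes summarize
the genetic architecture across diseases.  A small force-directed layout
(Fruchterman-Reingold) is included for visual inspection: diseases with
similar gene sets end up near each other.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx
import numpy as np


def build_bipartite(
    triples: Iterable[tuple[str, str, str]]
) -> nx.Graph:
    """Bipartite variant-gene network from (variant, gene, disease) triples.

    Edges are deduplicated; each variant node accumulates the set of
    diseases it is pleiotropic for.
    """
    g = nx.Graph()
    for triple in triples:
        try:
            variant, gene, disease = triple
        except (TypeError, ValueError):
            raise ValueError(f"malformed triple: {triple!r}") from None
        if not variant or not gene or not disease:
            raise ValueError(f"malformed triple: {triple!r}")
        if variant not in g:
            g.add_node(variant, kind="variant", diseases=set())
        g.nodes[variant]["diseases"].add(disease)
        g.add_node(gene, kind="gene")
        g.add_edge(variant, gene)
    return g


def compress_by_disease(bipartite: nx.Graph) -> nx.Graph:
    """Collapse all variants of one disease into a single disease node.

    Disease-gene edge weight = number of that disease's variants
    targeting the gene.
    """
    dg = nx.Graph()
    for node, data in bipartite.nodes(data=True):
        if data.get("kind") != "variant":
            continue
        diseases = data.get("diseases")
        if not diseases:
            raise ValueError(f"variant {node!r} has no disease label")
        for gene in bipartite.neighbors(node):
            for disease in diseases:
                if dg.has_edge(disease, gene):
                    dg[disease][gene]["weight"] += 1
                else:
                    dg.add_node(disease, kind="disease")
                    dg.add_node(gene, kind="gene")
                    dg.add_edge(disease, gene, weight=1)
    return dg


def shared_gene_summary(
    dg: nx.Graph, min_diseases: int = 3
) -> tuple[int, int, float]:
    """(n_shared, n_total, percentage) of genes shared by at least
    ``min_diseases`` diseases; percentage rounded to 2 decimals."""
    genes = [n for n, d in dg.nodes(data=True) if d.get("kind") == "gene"]
    if not genes:
        raise ValueError("network has no gene nodes")
    n_shared = sum(1 for g in genes if dg.degree(g) >= min_diseases)
    pct = round(100.0 * n_shared / len(genes), 2)
    return n_shared, len(genes), pct


def force_layout(
    g: nx.Graph,
    iterations: int = 100,
    seed: int = 0,
    k: float | None = None,
) -> dict:
    """Fruchterman-Reingold force-directed layout, deterministic per seed.

    Nodes repel with k^2/d and each edge pulls with d^2/k; positions are
    not rescaled, so an isolated connected pair settles at separation
    close to the natural spring length k.  A single node sits at the
    origin.
    """
    nodes = list(g.nodes())
    n = len(nodes)
    if n == 0:
        return {}
    if n == 1:
        return {nodes[0]: np.zeros(2)}
    if k is None:
        k = 1.0 / np.sqrt(n)
    idx = {v: i for i, v in enumerate(nodes)}
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-0.5, 0.5, size=(n, 2))
    edges = np.array([(idx[u], idx[v]) for u, v in g.edges()], dtype=int)
    t = 0.1 * max(1.0, k * np.sqrt(n))  # initial temperature
    dt = t / (iterations + 1)
    for _ in range(iterations):
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(delta, axis=-1)
        np.fill_diagonal(dist, 1.0)
        dist = np.maximum(dist, 1e-9)
        disp = (delta / dist[..., None] * (k * k / dist)[..., None]).sum(axis=1)
        if len(edges):
            d = pos[edges[:, 0]] - pos[edges[:, 1]]
            dn = np.maximum(np.linalg.norm(d, axis=1), 1e-9)
            pull = d / dn[:, None] * (dn * dn / k)[:, None]
            np.subtract.at(disp, edges[:, 0], pull)
            np.add.at(disp, edges[:, 1], pull)
        length = np.maximum(np.linalg.norm(disp, axis=1), 1e-9)
        pos += disp / length[:, None] * np.minimum(length, t)[:, None]
        t -= dt
    return {v: pos[i].copy() for v, i in idx.items()}
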