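"""Directed similarity graph and Leiden community detection.

Nodes are (dataset, group) pairs; a directed edge from A.i to B.j carries
the similarity of group i (dataset A) toward group j (dataset B).  Per
source node and external dataset only the top-n similarities are kept
(top_n = 1 gives one outward edge per external dataset).  Communities are
found with the Leiden algorithm (local moving, refinement, aggregation)
on the symmetrized graph; negative weights are shifted to be nonnegative
for detection only — exports keep the raw similarities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import igraph as ig
import leidenalg

from .similarity import SimilarityRecord

__all__ = ["SimilarityGraph", "build_graph", "find_communities", "export_graph", "plot_graph"]

Node = tuple[str, str]  # (dataset, group)


@dataclass
class SimilarityGraph:
    nodes: list[Node]
    edges: list[tuple[Node, Node, float]]  # (source, target, similarity)
    community_of: dict[Node, int] | None = None


def build_graph(
    records: Sequence[SimilarityRecord], top_n: int = 1
) -> SimilarityGraph:
    """Keep, per (source node, target dataset), the top_n similarities.

    Ties are broken lexicographically by target group; weights (including
    negative ones) are retained as-is.  The result depends only on the
    record set, not its order.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if not records:
        raise ValueError("no records")
    nodes: set[Node] = set()
    grouped: dict[tuple[Node, str], list[SimilarityRecord]] = {}
    for r in records:
        src: Node = (r.dataset_a, r.group_a)
        nodes.add(src)
        nodes.add((r.dataset_b, r.group_b))
        grouped.setdefault((src, r.dataset_b), []).append(r)
    edges = []
    for (src, _), recs in sorted(grouped.items()):
        recs = sorted(recs, key=lambda r: (-r.similarity, r.group_b))
        for r in recs[:top_n]:
            edges.append((src, (r.dataset_b, r.group_b), r.similarity))
    return SimilarityGraph(nodes=sorted(nodes), edges=sorted(edges))


def _to_igraph(graph: SimilarityGraph, directed: bool = True) -> ig.Graph:
    index = {n: i for i, n in enumerate(graph.nodes)}
    g = ig.Graph(directed=directed)
    g.add_vertices(len(graph.nodes))
    g.vs["name"] = [f"{d}:{grp}" for d, grp in graph.nodes]
    g.vs["dataset"] = [d for d, _ in graph.nodes]
    g.vs["group"] = [grp for _, grp in graph.nodes]
    g.add_edges([(index[s], index[t]) for s, t, _ in graph.edges])
    g.es["similarity"] = [w for _, _, w in graph.edges]
    return g


def find_communities(
    graph: SimilarityGraph, resolution: float = 1.0, seed: int = 0
) -> dict[Node, int]:
    """Leiden partition of the similarity graph.

    The directed graph is symmetrized (max similarity of the two
    directions) and weights shifted by −min(0, min weight) so they are
    nonnegative; the Leiden objective is modularity with a resolution
    parameter.  Community ids are 0-based, ordered by community size
    descending (ties by smallest member node).  Deterministic for a fixed
    seed.
    """
    if not graph.nodes:
        raise ValueError("empty graph")
    sym: dict[tuple[Node, Node], float] = {}
    for s, t, w in graph.edges:
        key = (s, t) if s <= t else (t, s)
        sym[key] = max(w, sym.get(key, float("-inf")))
    weights = list(sym.values())
    shift = -min(0.0, min(weights)) if weights else 0.0
    index = {n: i for i, n in enumerate(graph.nodes)}
    g = ig.Graph(directed=False)
    g.add_vertices(len(graph.nodes))
    g.add_edges([(index[s], index[t]) for (s, t) in sym])
    g.es["weight"] = [w + shift for w in weights]
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight" if len(sym) else None,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    membership = part.membership
    # relabel 0-based by size descending, ties by smallest member index
    sizes: dict[int, list[int]] = {}
    for v, c in enumerate(membership):
        sizes.setdefault(c, []).append(v)
    order = sorted(sizes, key=lambda c: (-len(sizes[c]), min(sizes[c])))
    relabel = {c: i for i, c in enumerate(order)}
    return {n: relabel[membership[index[n]]] for n in graph.nodes}


def export_graph(
    graph: SimilarityGraph, path: str | Path, format: str = "edgelist"
) -> None:
    """Serialize nodes, directed edges, weights and communities.

    ``edgelist``: TSV with columns source_dataset, source_group,
    target_dataset, target_group, similarity and, when communities were
    assigned, community_source / community_target.  ``graphml``: GraphML
    with the same attributes via igraph.
    """
    path = Path(path)
    comm = graph.community_of
    if format == "edgelist":
        cols = ["source_dataset", "source_group", "target_dataset", "target_group", "similarity"]
        if comm is not None:
            cols += ["community_source", "community_target"]
        lines = ["\t".join(cols)]
        for s, t, w in graph.edges:
            row = [s[0], s[1], t[0], t[1], f"{w:.10g}"]
            if comm is not None:
                row += [str(comm[s]), str(comm[t])]
            lines.append("\t".join(row))
        path.write_text("\n".join(lines) + "\n")
    elif format == "graphml":
        g = _to_igraph(graph, directed=True)
        if comm is not None:
            g.vs["community"] = [comm[n] for n in graph.nodes]
        g.write_graphml(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


def read_edgelist(path: str | Path) -> SimilarityGraph:
    """Read a graph written by :func:`export_graph` in edgelist format."""
    lines = Path(path).read_text().strip().split("\n")
    header = lines[0].split("\t")
    has_comm = "community_source" in header
    nodes: set[Node] = set()
    edges = []
    comm: dict[Node, int] = {}
    for line in lines[1:]:
        parts = line.split("\t")
        s: Node = (parts[0], parts[1])
        t: Node = (parts[2], parts[3])
        nodes.update((s, t))
        edges.append((s, t, float(parts[4])))
        if has_comm:
            comm[s] = int(parts[5])
            comm[t] = int(parts[6])
    return SimilarityGraph(
        nodes=sorted(nodes), edges=sorted(edges), community_of=comm if has_comm else None
    )


def plot_graph(graph: SimilarityGraph, path: str | Path, seed: int = 0) -> None:
    """Convenience PNG of the graph (deterministic force-directed layout)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = _to_igraph(graph, directed=True)
    import random

    random.seed(seed)
    layout = g.layout_fruchterman_reingold(niter=200)
    xy = [tuple(p) for p in layout]
    comm = graph.community_of or {}
    colors = [comm.get(n, 0) for n in graph.nodes]
    fig, ax = plt.subplots(figsize=(6, 6))
    for s, t, w in graph.edges:
        i, j = graph.nodes.index(s), graph.nodes.index(t)
        ax.annotate(
            "",
            xy=xy[j],
            xytext=xy[i],
            arrowprops=dict(arrowstyle="->", color="grey", lw=0.8),
        )
    ax.scatter([p[0] for p in xy], [p[1] for p in xy], c=colors, cmap="tab10", zorder=3)
    for (d, grp), (x, y) in zip(graph.nodes, xy):
        ax.annotate(f"{d}:{grp}", (x, y), fontsize=6, xytext=(3, 3), textcoords="offset points")
    ax.set_axis_off()
    fig.savefig(path, dpi=150)
    plt.close(fig)
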