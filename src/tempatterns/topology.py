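"""Sensor-topology graph from elementary patterns, with strength pruning.

Every sensor is a node; each detected elementary pattern joins its two
sensors with an undirected edge whose strength is the larger of the two
directional pattern strengths.  The pruning rule removes an edge (i, j) when
some third sensor k currently holds strictly stronger edges to both i and j
— a triangle shortcut elimination that recovers the corridor "roadmap"
(a Voronoi-graph-like proximity map) of the environment without any
coordinates.  Edges are considered in ascending strength, sequentially
against the partially pruned graph.
"""

from __future__ import annotations

import csv
from typing import Iterable, Sequence

import networkx as nx

from .ci_search import TPattern

__all__ = ["build_graph", "prune_graph", "export_graph", "import_graph_csv"]


def build_graph(patterns: Sequence[TPattern]) -> nx.Graph:
    """Undirected sensor graph from elementary (depth-2) patterns.

    Self-patterns contribute their node but no edge; for a pair detected in
    both directions the edge keeps the maximum strength.
    """
    g = nx.Graph()
    for pat in patterns:
        if pat.depth != 2:
            raise ValueError("the topology graph is built from elementary patterns only")
        if pat.strength is None:
            raise ValueError(f"pattern {pat.left}->{pat.right} carries no strength")
        g.add_node(pat.left)
        g.add_node(pat.right)
        if pat.left == pat.right:
            continue
        if g.has_edge(pat.left, pat.right):
            g[pat.left][pat.right]["strength"] = max(
                g[pat.left][pat.right]["strength"], pat.strength
            )
        else:
            g.add_edge(pat.left, pat.right, strength=pat.strength)
    return g


def _edge_key(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


def prune_graph(g: nx.Graph, against_original: bool = False) -> nx.Graph:
    """Remove triangle shortcuts, weakest edges first.

    Edge (i, j) goes when some k has strictly stronger edges to both i and j.
    By default removals act sequentially against the current, partially
    pruned graph; ``against_original`` evaluates the condition on the input
    graph instead (documented alternative).  The operation is idempotent.
    """
    pruned = g.copy()
    reference = g if against_original else pruned
    edges = sorted(
        g.edges(data="strength"), key=lambda e: (e[2], _edge_key(e[0], e[1]))
    )
    for u, v, s in edges:
        if not pruned.has_edge(u, v):
            continue
        for k in set(reference[u]) & set(reference[v]):
            if (
                reference[u][k]["strength"] > s
                and reference[v][k]["strength"] > s
            ):
                pruned.remove_edge(u, v)
                break
    return pruned


def export_graph(g: nx.Graph, path, fmt: str = "csv") -> None:
    """Write the graph as edge-list CSV, DOT or GraphML (deterministic order)."""
    if fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "target", "strength"])
            for u, v in sorted(_edge_key(a, b) for a, b in g.edges):
                writer.writerow([u, v, repr(float(g[u][v]["strength"]))])
            for node in sorted(n for n in g.nodes if g.degree(n) == 0):
                writer.writerow([node, "", ""])
    elif fmt == "dot":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("graph topology {\n")
            for node in sorted(g.nodes):
                fh.write(f'  "{node}";\n')
            for u, v in sorted(_edge_key(a, b) for a, b in g.edges):
                fh.write(f'  "{u}" -- "{v}" [label="{g[u][v]["strength"]:.3g}"];\n')
            fh.write("}\n")
    elif fmt == "graphml":
        h = nx.Graph()
        h.add_nodes_from(sorted(g.nodes))
        for u, v in sorted(_edge_key(a, b) for a, b in g.edges):
            h.add_edge(u, v, strength=float(g[u][v]["strength"]))
        nx.write_graphml(h, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def import_graph_csv(path) -> nx.Graph:
    """Read back an edge-list CSV written by :func:`export_graph`."""
    g = nx.Graph()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["source", "target", "strength"]:
            raise ValueError(f"{path}: not a topology edge-list CSV")
        for row in reader:
            if not row or not row[0]:
                continue
            if len(row) >= 2 and row[1]:
                g.add_edge(row[0], row[1], strength=float(row[2]))
            else:
                g.add_node(row[0])
    return g
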