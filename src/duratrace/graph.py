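"""Innervation graph: fuse per-axon traces and report complexity metrics.

Traced centerlines are merged on their shared pixel grid: identical pixel
steps contributed by several traces (axons traced from a common stem) are
deduplicated, termini and crossings closer than ``merge_radius`` are fused
into single nodes, and the resulting undirected graph yields the two
innervation-complexity metrics: total axonal length (µm) and the number of
axonal endpoints (degree-1 nodes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .trace import AxonTrace, polyline_length

__all__ = ["InnervationGraph", "build_graph", "graph_metrics"]


@dataclass
class InnervationGraph:
    """Undirected graph of centerline segments.

    ``g`` is a networkx MultiGraph whose nodes carry ``position`` (µm, x-y-z)
    and ``kind`` ("endpoint" or "junction") and whose edges carry
    ``length`` (µm) and ``polyline``.
    """

    g: nx.MultiGraph = field(default_factory=nx.MultiGraph)

    @property
    def total_length(self) -> float:
        return float(sum(d["length"] for *_, d in self.g.edges(data=True)))

    @property
    def endpoint_count(self) -> int:
        return sum(1 for n in self.g.nodes if self.g.degree(n) == 1)


def _pixel_chain_graph(traces: list[AxonTrace]) -> tuple[nx.Graph, dict]:
    """Pixel-level graph of deduplicated centerline steps.

    Nodes are (row, col) centerline pixels; each unordered pair of pixels
    consecutive in some trace becomes one edge weighted by the 3D µm distance
    between the pixels' lifted positions. Shared sub-paths therefore count
    once.
    """
    pos3: dict[tuple[int, int], np.ndarray] = {}
    H = nx.Graph()
    for t in traces:
        pts2 = [tuple(p) for p in t.centerline.points2d]
        pts3 = t.centerline.points3d
        if pts3 is None:
            raise ValueError("traces must carry 3D morphometry (measure_axon)")
        for p, q in zip(pts2, pts3):
            pos3.setdefault(p, np.asarray(q, float))
        H.add_nodes_from(pts2)
        for a, b in zip(pts2[:-1], pts2[1:]):
            if a != b and not H.has_edge(a, b):
                H.add_edge(a, b, length=float(np.linalg.norm(pos3[a] - pos3[b])))
    return H, pos3


def build_graph(traces: list[AxonTrace], merge_radius: float = 3.0) -> InnervationGraph:
    """Merge traces into an innervation graph.

    Special pixels (degree != 2 in the deduplicated step graph) become graph
    nodes; chains of degree-2 pixels between them become edges. Special nodes
    whose positions lie within ``merge_radius`` µm of each other are fused
    (union of clusters, centroid position); fused nodes left with degree 2
    are spliced out so only endpoints and junctions remain.
    """
    out = InnervationGraph()
    if not traces:
        return out
    if merge_radius < 0:
        raise ValueError("merge_radius must be >= 0")
    H, pos3 = _pixel_chain_graph(traces)

    special = [n for n in H.nodes if H.degree(n) != 2]
    if not special:  # a pure cycle; anchor it at an arbitrary pixel
        special = [next(iter(H.nodes))]
    special_set = set(special)

    # walk chains between special pixels
    coarse = nx.MultiGraph()
    coarse.add_nodes_from(special)
    visited_edges = set()
    for s in special:
        for nb in H.neighbors(s):
            if (s, nb) in visited_edges:
                continue
            chain = [s, nb]
            prev, cur = s, nb
            while cur not in special_set:
                nxts = [x for x in H.neighbors(cur) if x != prev]
                if not nxts:
                    break
                prev, cur = cur, nxts[0]
                chain.append(cur)
            visited_edges.add((s, nb))
            visited_edges.add((chain[-1], chain[-2]))
            poly = np.array([pos3[p] for p in chain])
            coarse.add_edge(chain[0], chain[-1], length=polyline_length(poly), polyline=poly)

    # fuse special nodes within merge_radius (single-linkage union-find)
    nodes = list(coarse.nodes)
    parent = {n: n for n in nodes}

    def find(n):
        while parent[n] != n:
            parent[n] = parent[parent[n]]
            n = parent[n]
        return n

    if merge_radius > 0 and len(nodes) > 1:
        positions = np.array([pos3[n] for n in nodes])
        from scipy.spatial import cKDTree

        tree = cKDTree(positions)
        for i, j in tree.query_pairs(merge_radius):
            ri, rj = find(nodes[i]), find(nodes[j])
            if ri != rj:
                parent[ri] = rj

    merged = nx.MultiGraph()
    clusters: dict = {}
    for n in nodes:
        clusters.setdefault(find(n), []).append(n)
    node_map = {}
    for root, members in clusters.items():
        centroid = np.mean([pos3[m] for m in members], axis=0)
        node_map.update({m: root for m in members})
        merged.add_node(root, position=centroid)
    for u, v, d in coarse.edges(data=True):
        mu, mv = node_map[u], node_map[v]
        if mu == mv and d["length"] <= merge_radius:
            continue  # a chain collapsed inside one fused node
        merged.add_edge(mu, mv, **d)

    _splice_degree2(merged)
    for n in merged.nodes:
        merged.nodes[n]["kind"] = "endpoint" if merged.degree(n) == 1 else "junction"
    out.g = merged
    return out


def _splice_degree2(g: nx.MultiGraph) -> None:
    """Replace pass-through nodes (degree 2, two distinct neighbors) by one edge."""
    changed = True
    while changed:
        changed = False
        for n in list(g.nodes):
            if g.degree(n) != 2:
                continue
            inc = list(g.edges(n, keys=True, data=True))
            if len(inc) != 2:
                continue
            (u1, v1, k1, d1), (u2, v2, k2, d2) = inc
            a = v1 if u1 == n else u1
            b = v2 if u2 == n else u2
            if a == n or b == n:
                continue  # self loop, leave it
            p1 = d1["polyline"] if u1 == n else d1["polyline"][::-1]
            p2 = d2["polyline"] if u2 == n else d2["polyline"][::-1]
            poly = np.vstack([p1[::-1], p2[1:]])
            g.remove_edge(u1, v1, k1)
            g.remove_edge(u2, v2, k2)
            g.remove_node(n)
            g.add_edge(a, b, length=d1["length"] + d2["length"], polyline=poly)
            changed = True
            break


def graph_metrics(g: InnervationGraph) -> dict[str, float]:
    """The two innervation-complexity metrics of the merged graph."""
    return {
        "total_length": g.total_length,
        "endpoint_count": g.endpoint_count,
    }
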