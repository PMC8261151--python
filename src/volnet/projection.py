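"""Projection of inferred connections onto the reaction network.

Each retained source->target connection is mapped to the shortest
directed path between the corresponding metabolite nodes in the
bipartite metabolite/gene reaction graph (unit edge weights). A synergy
triad is rendered as the "forked" pair of paths from its two sources to
the shared target. Pathways supported by at least two projected
connections are extracted as sub-networks.

Determinism: when several shortest paths tie, the lexicographically
smallest node-id sequence wins; when a channel maps to several graph
node ids, the (source id, target id) combination with the globally
shortest path wins (ties again lexicographic). Connections with no
directed route (or no annotation) are kept with status
``"unprojectable"`` rather than dropped.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .io import AnnotationTable, ReactionGraph
from .network import DirectedConnection, SynergyTriad

__all__ = ["ProjectedPath", "SubNetwork", "project_connection", "project_triad",
           "extract_subnetworks", "export_network", "shortest_path_lex"]


@dataclass
class ProjectedPath:
    source_mz: float
    target_mz: float
    nodes: tuple[str, ...] = ()
    length: int = -1                      # edge count; -1 when unprojectable
    pathway_ids: frozenset = frozenset()  # union over traversed edges
    status: str = "projected"             # or "unprojectable"
    reason: str = ""
    kind: str = "unique"                  # "unique" | "synergy-fork"


@dataclass
class SubNetwork:
    pathway_id: str
    name: str
    members: list[ProjectedPath]
    graph: nx.DiGraph = field(default_factory=nx.DiGraph)


# ---------------------------------------------------------------------------
# deterministic shortest path


def _distances_to(graph: nx.DiGraph, target: str) -> dict[str, int]:
    """BFS distances to ``target`` along edge direction (reverse BFS)."""
    dist = {target: 0}
    queue = deque([target])
    while queue:
        v = queue.popleft()
        for u in graph.predecessors(v):
            if u not in dist:
                dist[u] = dist[v] + 1
                queue.append(u)
    return dist


def shortest_path_lex(graph: nx.DiGraph, source: str,
                      target: str) -> list[str] | None:
    """Shortest directed path; among equals, the lexicographically
    smallest node sequence. ``None`` when no path exists."""
    if source not in graph or target not in graph:
        return None
    dist = _distances_to(graph, target)
    if source not in dist:
        return None
    path = [source]
    node = source
    while node != target:
        d = dist[node]
        nxt = min(v for v in graph.successors(node)
                  if dist.get(v, -1) == d - 1)
        path.append(nxt)
        node = nxt
    return path


def _edge_pathways(graph: nx.DiGraph, nodes: tuple[str, ...]) -> frozenset:
    out = set()
    for u, v in zip(nodes[:-1], nodes[1:]):
        out |= set(graph.edges[u, v].get("pathways", ()))
    return frozenset(out)


# ---------------------------------------------------------------------------
# projection


def project_connection(connection: DirectedConnection | tuple[float, float],
                       annotation: AnnotationTable,
                       rg: ReactionGraph) -> ProjectedPath:
    """Map one source->target connection onto the reaction graph.

    When a channel's annotation lists several candidate node ids, every
    (source id, target id) combination is tried and the globally
    shortest projection wins (candidates logged via the returned path's
    ``reason`` on failure).
    """
    if isinstance(connection, DirectedConnection):
        s_mz, t_mz = connection.source, connection.target
    else:
        s_mz, t_mz = connection
    ann_s = annotation.for_channel(s_mz)
    ann_t = annotation.for_channel(t_mz)
    for ann, mz, role in ((ann_s, s_mz, "source"), (ann_t, t_mz, "target")):
        if ann is None or not ann.node_ids:
            return ProjectedPath(s_mz, t_mz, status="unprojectable",
                                 reason=f"{role} m/z {mz:g} has no graph node id")

    best: list[str] | None = None
    for sid in sorted(ann_s.node_ids):
        for tid in sorted(ann_t.node_ids):
            if sid == tid:
                continue
            p = shortest_path_lex(rg.graph, sid, tid)
            if p is None:
                continue
            if best is None or len(p) < len(best) or \
                    (len(p) == len(best) and p < best):
                best = p
    if best is None:
        return ProjectedPath(s_mz, t_mz, status="unprojectable",
                             reason="no directed path in reaction graph")
    return ProjectedPath(s_mz, t_mz, nodes=tuple(best), length=len(best) - 1,
                         pathway_ids=_edge_pathways(rg.graph, tuple(best)))


def project_triad(triad: SynergyTriad, annotation: AnnotationTable,
                  rg: ReactionGraph) -> list[ProjectedPath]:
    """Project a synergy triad as its two source->target forks."""
    out = []
    for src in (triad.source1, triad.source2):
        p = project_connection((src, triad.target), annotation, rg)
        p.kind = "synergy-fork"
        out.append(p)
    return out


def extract_subnetworks(paths: list[ProjectedPath],
                        rg: ReactionGraph,
                        min_members: int = 2) -> list[SubNetwork]:
    """Pathways supported by >= ``min_members`` projected connections.

    A path is a member of a pathway if at least one of its edges carries
    that pathway id; one path crossing two pathways counts for both. The
    returned sub-networks carry the subgraph induced by their members'
    nodes and edges, and are sorted by pathway id (order-independent).
    """
    members: dict[str, list[ProjectedPath]] = {}
    for p in paths:
        if p.status != "projected":
            continue
        for pid in p.pathway_ids:
            members.setdefault(pid, []).append(p)
    out = []
    for pid in sorted(members):
        mem = members[pid]
        if len(mem) < min_members:
            continue
        sub = nx.DiGraph()
        for p in mem:
            for u, v in zip(p.nodes[:-1], p.nodes[1:]):
                sub.add_node(u, **rg.graph.nodes[u])
                sub.add_node(v, **rg.graph.nodes[v])
                sub.add_edge(u, v, **rg.graph.edges[u, v])
        out.append(SubNetwork(pathway_id=pid, name=rg.pathways.get(pid, pid),
                              members=mem, graph=sub))
    return out


# ---------------------------------------------------------------------------
# export


def export_network(subnetworks: list[SubNetwork], paths: list[ProjectedPath],
                   rg: ReactionGraph, out_dir) -> dict[str, Path]:
    """Write GraphML + flat tables for the projected network.

    ``network.graphml`` holds the union of all projected paths with node
    attributes ``kind`` and ``detected`` (True for metabolites that are
    endpoints of a projected connection, i.e. detected as volatile
    compounds, False for pass-through nodes); ``edges.tsv``,
    ``subnetworks.tsv`` and ``unprojectable.tsv`` are flat tables.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    union = nx.DiGraph()
    detected: set[str] = set()
    for p in paths:
        if p.status != "projected":
            continue
        detected.add(p.nodes[0])
        detected.add(p.nodes[-1])
        for u, v in zip(p.nodes[:-1], p.nodes[1:]):
            for node in (u, v):
                union.add_node(node, kind=rg.graph.nodes[node]["kind"],
                               label=rg.graph.nodes[node].get("label", node))
            d = rg.graph.edges[u, v]
            union.add_edge(u, v, reaction=d.get("reaction", ""),
                           pathways=";".join(sorted(d.get("pathways", ()))))
    for n in union.nodes:
        union.nodes[n]["detected"] = n in detected

    files = {}
    graphml = out_dir / "network.graphml"
    nx.write_graphml(union, graphml)
    files["graphml"] = graphml

    edge_rows = [{"from": u, "to": v, "reaction": d["reaction"],
                  "pathways": d["pathways"]}
                 for u, v, d in union.edges(data=True)]
    edges_path = out_dir / "edges.tsv"
    pd.DataFrame(edge_rows, columns=["from", "to", "reaction", "pathways"]) \
        .to_csv(edges_path, sep="\t", index=False)
    files["edges"] = edges_path

    sub_rows = [{"pathway_id": s.pathway_id, "name": s.name,
                 "n_members": len(s.members),
                 "members": ";".join(f"{m.source_mz:g}->{m.target_mz:g}"
                                     for m in s.members)}
                for s in subnetworks]
    sub_path = out_dir / "subnetworks.tsv"
    pd.DataFrame(sub_rows, columns=["pathway_id", "name", "n_members",
                                    "members"]) \
        .to_csv(sub_path, sep="\t", index=False)
    files["subnetworks"] = sub_path

    un_rows = [{"source_mz": p.source_mz, "target_mz": p.target_mz,
                "reason": p.reason}
               for p in paths if p.status == "unprojectable"]
    un_path = out_dir / "unprojectable.tsv"
    pd.DataFrame(un_rows, columns=["source_mz", "target_mz", "reason"]) \
        .to_csv(un_path, sep="\t", index=False)
    files["unprojectable"] = un_path
    return files
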