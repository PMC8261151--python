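"""Readers and writers for all external formats.

Canonical matrix format: wide delimited text (tab or comma,
auto-detected), first column time, header row of m/z labels at 3-decimal
precision, missing cells empty (never sentinel numbers). The reaction
graph travels as one tab-separated file with three sections
(``[nodes]``, ``[edges]``, ``[pathways]``); channel annotations as a flat
table (m/z, compound, graph node ids, optional parent fragment).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .panel import FluxPanel, IonCountMatrix, PanelFormatError

__all__ = [
    "read_ion_counts", "write_ion_counts",
    "read_panel", "write_panel",
    "read_reaction_graph", "write_reaction_graph", "ReactionGraph",
    "read_annotation", "ChannelAnnotation", "AnnotationTable",
    "GraphFormatError",
]

MZ_TOLERANCE = 0.005  # Th; matches the 3-decimal m/z labelling


class GraphFormatError(ValueError):
    """Reaction-graph file violates the format or bipartiteness."""


def _sniff_sep(path) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def _parse_mz_header(labels, where: str) -> list[float]:
    mz = []
    for lab in labels:
        try:
            mz.append(float(lab))
        except ValueError as exc:
            raise PanelFormatError(f"{where}: non-numeric m/z label {lab!r}") from exc
    dupes = {m for m in mz if mz.count(m) > 1}
    if dupes:
        raise PanelFormatError(f"{where}: duplicated m/z header {sorted(dupes)}")
    return mz


# ---------------------------------------------------------------------------
# ion-count matrices


def read_ion_counts(path, sep: str | None = None,
                    chamber_id: str = "") -> IonCountMatrix:
    """Read a wide ion-count table (first column seconds, header m/z).

    Empty cells become missing (``NaN``); non-monotonic timestamps,
    duplicate m/z headers and negative counts are rejected.
    """
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    if df.shape[1] < 2:
        raise PanelFormatError(f"{path}: need a time column and >=1 channel")
    mz = _parse_mz_header(df.columns[1:], str(path))
    df.index = df.iloc[:, 0].astype(float)
    df = df.iloc[:, 1:]
    df.columns = mz
    return IonCountMatrix(df.astype(float), chamber_id=chamber_id or str(path))


def write_ion_counts(matrix: IonCountMatrix, path, sep: str = "\t") -> None:
    df = matrix.data.copy()
    df.columns = [f"{c:.3f}" for c in df.columns]
    df.index.name = "time_s"
    df.to_csv(path, sep=sep, float_format="%.6g", na_rep="")


# ---------------------------------------------------------------------------
# flux panels


def write_panel(panel: FluxPanel, path, sep: str = "\t") -> None:
    """Write a panel: time_min, phase, then one column per m/z channel."""
    df = pd.DataFrame({"time_min": panel.times, "phase": panel.phases})
    for c in panel.channels:
        df[f"{c:.3f}"] = panel.data[c].to_numpy()
    df.to_csv(path, sep=sep, index=False, float_format="%.10g", na_rep="")


def read_panel(path, sep: str | None = None) -> FluxPanel:
    """Read a panel written by :func:`write_panel`; validates the grid."""
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    required = {"time_min", "phase"}
    if not required.issubset(df.columns):
        raise PanelFormatError(f"{path}: missing columns {required - set(df.columns)}")
    mz = _parse_mz_header([c for c in df.columns if c not in required], str(path))
    t = df["time_min"].to_numpy(dtype=float)
    if len(t) >= 2:
        steps = np.diff(t)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise PanelFormatError(f"{path}: irregular time step")
    phases = df["phase"].astype(str).to_numpy()
    wetup = None
    wet_idx = np.where(phases == "wet")[0]
    if len(wet_idx):
        if not np.all(phases[wet_idx[0]:] == "wet") or not np.all(
                phases[:wet_idx[0]] == "dry"):
            raise PanelFormatError(f"{path}: phase labels do not split at one wet-up")
        wetup = float(t[wet_idx[0]])
    data = df.drop(columns=list(required)).astype(float)
    data.columns = mz
    data.index = t
    return FluxPanel(data, wetup_time=wetup)


# ---------------------------------------------------------------------------
# reaction graph


@dataclass
class ReactionGraph:
    """Directed bipartite metabolite/gene graph with pathway labels.

    ``graph`` is a :class:`networkx.DiGraph` whose nodes carry
    ``kind`` (``"metabolite"`` or ``"gene"``) and ``label`` attributes
    and whose edges carry ``pathways`` (frozenset of pathway ids) and
    ``reaction`` attributes.
    """

    graph: nx.DiGraph
    pathways: dict[str, str] = field(default_factory=dict)  # id -> name

    def __post_init__(self) -> None:
        for u, v in self.graph.edges():
            ku = self.graph.nodes[u].get("kind")
            kv = self.graph.nodes[v].get("kind")
            if ku == kv:
                raise GraphFormatError(
                    f"bipartiteness violation: edge {u}->{v} joins two {ku} nodes")
            for pid in self.graph.edges[u, v].get("pathways", ()):
                if pid not in self.pathways:
                    raise GraphFormatError(
                        f"edge {u}->{v} references unknown pathway {pid!r}")

    def add_manual_edges(self, edges) -> None:
        """Add user-curated reactions: iterable of
        (from, to, reaction_id, pathway_ids). Endpoints must exist."""
        for u, v, rid, pids in edges:
            for node in (u, v):
                if node not in self.graph:
                    raise GraphFormatError(f"manual edge references unknown node {node!r}")
            self.graph.add_edge(u, v, reaction=rid, pathways=frozenset(pids))
        self.__post_init__()

    @property
    def metabolites(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == "metabolite"}


def read_reaction_graph(path) -> ReactionGraph:
    """Parse the three-section reaction-graph file.

    Sections are introduced by ``[nodes]``, ``[edges]``, ``[pathways]``
    header lines; rows are tab-separated. Edges must alternate
    metabolite/gene endpoints and may carry several semicolon-separated
    pathway ids.
    """
    g = nx.DiGraph()
    pathways: dict[str, str] = {}
    edge_rows: list[tuple[str, str, str, tuple[str, ...]]] = []
    section = None
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            low = line.strip().lower()
            if low in ("[nodes]", "[edges]", "[pathways]"):
                section = low[1:-1]
                continue
            parts = line.split("\t")
            if section == "nodes":
                if len(parts) < 2:
                    raise GraphFormatError(f"{path}:{ln}: node row needs id and kind")
                nid, kind = parts[0], parts[1]
                if kind not in ("metabolite", "gene"):
                    raise GraphFormatError(f"{path}:{ln}: unknown node kind {kind!r}")
                label = parts[2] if len(parts) > 2 else nid
                g.add_node(nid, kind=kind, label=label)
            elif section == "edges":
                if len(parts) < 2:
                    raise GraphFormatError(f"{path}:{ln}: edge row needs from and to")
                u, v = parts[0], parts[1]
                rid = parts[2] if len(parts) > 2 else ""
                pids = tuple(p for p in (parts[3].split(";") if len(parts) > 3 else [])
                             if p)
                edge_rows.append((u, v, rid, pids))
            elif section == "pathways":
                if len(parts) < 2:
                    raise GraphFormatError(f"{path}:{ln}: pathway row needs id and name")
                pathways[parts[0]] = parts[1]
            else:
                raise GraphFormatError(f"{path}:{ln}: row outside any section")
    for u, v, rid, pids in edge_rows:
        for node in (u, v):
            if node not in g:
                raise GraphFormatError(f"{path}: edge references unknown node {node!r}")
        g.add_edge(u, v, reaction=rid, pathways=frozenset(pids))
    return ReactionGraph(g, pathways)


def write_reaction_graph(rg: ReactionGraph, path) -> None:
    buf = _io.StringIO()
    buf.write("[nodes]\n")
    for n, d in sorted(rg.graph.nodes(data=True)):
        buf.write(f"{n}\t{d['kind']}\t{d.get('label', n)}\n")
    buf.write("[edges]\n")
    for u, v, d in sorted(rg.graph.edges(data=True)):
        pids = ";".join(sorted(d.get("pathways", ())))
        buf.write(f"{u}\t{v}\t{d.get('reaction', '')}\t{pids}\n")
    buf.write("[pathways]\n")
    for pid, name in sorted(rg.pathways.items()):
        buf.write(f"{pid}\t{name}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# channel annotation


@dataclass(frozen=True)
class ChannelAnnotation:
    mz: float
    compound: str
    node_ids: tuple[str, ...] = ()
    fragment_of: float | None = None
    matched_channel: float | None = None   # panel channel within tolerance
    projectable: bool = True


@dataclass
class AnnotationTable:
    rows: list[ChannelAnnotation]
    unmatched: list[ChannelAnnotation] = field(default_factory=list)

    def for_channel(self, mz: float, tol: float = MZ_TOLERANCE) -> ChannelAnnotation | None:
        best, best_d = None, tol
        for r in self.rows:
            ref = r.matched_channel if r.matched_channel is not None else r.mz
            d = abs(ref - mz)
            if d <= best_d:
                best, best_d = r, d
        return best


def read_annotation(path, panel: FluxPanel | None = None,
                    sep: str | None = None,
                    tol: float = MZ_TOLERANCE) -> AnnotationTable:
    """Read the m/z -> compound / graph-node mapping table.

    Columns: ``mz``, ``compound``, ``node_ids`` (semicolon-separated,
    may be empty -> flagged non-projectable), optional ``fragment_of``.
    When a panel is given, each row is matched to a panel channel within
    ``tol`` Th; unmatched rows are kept separately (never fatal).
    """
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    if not {"mz", "compound"}.issubset(df.columns):
        raise PanelFormatError(f"{path}: annotation needs 'mz' and 'compound' columns")
    channels = np.array(panel.channels) if panel is not None else None
    rows, unmatched = [], []
    for _, row in df.iterrows():
        ids = ()
        if "node_ids" in df.columns and isinstance(row.get("node_ids"), str):
            ids = tuple(p for p in row["node_ids"].split(";") if p)
        frag = None
        if "fragment_of" in df.columns and pd.notna(row.get("fragment_of")):
            frag = float(row["fragment_of"])
        mz = float(row["mz"])
        matched = None
        if channels is not None and len(channels):
            d = np.abs(channels - mz)
            if d.min() <= tol:
                matched = float(channels[np.argmin(d)])
        ann = ChannelAnnotation(mz=mz, compound=str(row["compound"]),
                                node_ids=ids, fragment_of=frag,
                                matched_channel=matched,
                                projectable=bool(ids))
        if channels is not None and matched is None:
            unmatched.append(ann)
        else:
            rows.append(ann)
    return AnnotationTable(rows=rows, unmatched=unmatched)
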