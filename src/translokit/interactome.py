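"""Protein–protein interaction network topology: degree and bridgeness.

The translocation model uses two network features per protein: its degree
(number of distinct interactome neighbours) and its bridgeness, a centrality
that is high for proteins whose interactions span several overlapping network
modules (protein mega-complexes) and low for module-internal proteins.
Bridgeness is defined only on the giant component of the interactome.

Bridgeness here is an overlapping-membership score: modules are detected on
the giant component, each node receives a membership distribution p(m|node)
proportional to how many of its links (plus itself) fall in module m, and

    bridgeness(node) = 1 - sum_m p(m|node)**2

i.e. one minus the Simpson concentration of the membership distribution.
A node entirely inside one module scores 0; a node splitting its links
evenly between two modules scores 1/2.  The score lies in [0, 1).  Absolute
values are on this package's scale, not on the scale of any external module
detector; thresholds calibrated elsewhere do not transfer (see docs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, TextIO

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

_HEADER_HINTS = ("interactor", "protein", "uniprot", "source", "target")


class InteractomeError(ValueError):
    """Malformed edge input or an operation on an unsuitable graph."""


@dataclass(frozen=True)
class NodeTopology:
    """Per-node topological features of the interactome."""

    protein_id: str
    degree: int
    bridgeness: float | None
    in_giant_component: bool


def load_edges(edge_stream: TextIO | Iterable[str]) -> nx.Graph:
    """Read a TSV edge list into a simple undirected graph.

    The first two columns are the interactor ids; further columns (ComPPI
    localization/score columns) are ignored.  A header row is auto-detected.
    Self-loops and duplicate edges are dropped with logged counts.  A row
    with fewer than two columns raises :class:`InteractomeError` naming the
    line.
    """
    graph = nx.Graph()
    self_loops = 0
    duplicates = 0
    first_data_row = True
    for lineno, raw in enumerate(edge_stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise InteractomeError(
                f"edge list line {lineno}: expected at least 2 tab-separated "
                f"columns, got {len(fields)}"
            )
        a, b = fields[0].strip(), fields[1].strip()
        if first_data_row:
            first_data_row = False
            lowered = (a + " " + b).lower()
            if any(hint in lowered for hint in _HEADER_HINTS):
                continue  # header row
        if a == b:
            self_loops += 1
            graph.add_node(a)
            continue
        if graph.has_edge(a, b):
            duplicates += 1
            continue
        graph.add_edge(a, b)
    if self_loops or duplicates:
        logger.info(
            "dropped %d self-loop(s) and %d duplicate edge(s)",
            self_loops,
            duplicates,
        )
    return graph


def giant_component(graph: nx.Graph) -> nx.Graph:
    """Node-induced subgraph of the largest connected component.

    Size ties are broken in favour of the component containing the
    lexicographically smallest member id.  Raises on an empty graph.
    """
    if graph.number_of_nodes() == 0:
        raise InteractomeError("cannot take the giant component of an empty graph")
    components = list(nx.connected_components(graph))
    best = min(components, key=lambda c: (-len(c), min(c)))
    excluded = graph.number_of_nodes() - len(best)
    if excluded:
        logger.info("giant component excludes %d node(s)", excluded)
    return graph.subgraph(best).copy()


def degree(graph: nx.Graph, node: str) -> int:
    """Number of distinct neighbours of ``node`` (self-loops never count)."""
    if node not in graph:
        raise KeyError(f"unknown node: {node}")
    return graph.degree[node]


def _detect_modules(graph: nx.Graph, method: str, seed: int) -> list[set]:
    if method == "modularity":
        return [set(c) for c in nx.community.greedy_modularity_communities(graph)]
    if method == "label_propagation":
        return [
            set(c)
            for c in nx.community.asyn_lpa_communities(graph, seed=seed)
        ]
    raise ValueError(f"unknown community method: {method!r}")


def bridgeness(
    graph: nx.Graph,
    method: str = "modularity",
    seed: int = 0,
) -> dict[str, float]:
    """Overlapping-membership bridgeness for every node of a connected graph.

    Parameters
    ----------
    graph : connected undirected graph (call :func:`giant_component` first).
    method : ``"modularity"`` (greedy modularity maximization; deterministic,
        the default) or ``"label_propagation"`` (seeded asynchronous LPA).
    seed : RNG seed for stochastic community methods; ignored by the default.

    Returns ``{node: 1 - sum_m p(m|node)**2}`` with membership
    ``p(m|node)`` proportional to the node's link count into module m,
    counting the node itself once in its home module.
    """
    if graph.number_of_nodes() == 0:
        raise InteractomeError("bridgeness of an empty graph is undefined")
    if not nx.is_connected(graph):
        raise InteractomeError(
            "graph is disconnected; compute bridgeness on giant_component(graph)"
        )
    modules = _detect_modules(graph, method, seed)
    home = {node: idx for idx, module in enumerate(modules) for node in module}
    scores: dict[str, float] = {}
    for node in graph.nodes:
        counts: dict[int, float] = {home[node]: 1.0}
        for neighbour in graph.neighbors(node):
            m = home[neighbour]
            counts[m] = counts.get(m, 0.0) + 1.0
        total = sum(counts.values())
        scores[node] = 1.0 - sum((c / total) ** 2 for c in counts.values())
    return scores


def topology_table(
    graph: nx.Graph,
    method: str = "modularity",
    seed: int = 0,
) -> list[NodeTopology]:
    """Degree for every node; bridgeness for giant-component nodes only.

    Nodes outside the giant component get ``bridgeness=None`` — the model's
    bridgeness indicator features then evaluate false for them.
    """
    rows: list[NodeTopology] = []
    if graph.number_of_nodes() == 0:
        return rows
    giant = giant_component(graph)
    bridge = bridgeness(giant, method=method, seed=seed)
    for node in graph.nodes:
        rows.append(
            NodeTopology(
                protein_id=node,
                degree=graph.degree[node],
                bridgeness=bridge.get(node),
                in_giant_component=node in giant,
            )
        )
    return rows


def topology_frame(rows: list[NodeTopology]) -> pd.DataFrame:
    """Topology rows as a DataFrame (bridgeness NaN outside the giant component)."""
    return pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in rows],
            "degree": [r.degree for r in rows],
            "bridgeness": [r.bridgeness for r in rows],
            "in_giant_component": [r.in_giant_component for r in rows],
        }
    )


def write_topology(rows: list[NodeTopology], sink: TextIO) -> None:
    """Write the topology table as TSV (empty bridgeness cell = undefined)."""
    sink.write("protein_id\tdegree\tbridgeness\tin_giant_component\n")
    for r in rows:
        b = "" if r.bridgeness is None else repr(r.bridgeness)
        sink.write(
            f"{r.protein_id}\t{r.degree}\t{b}\t{str(r.in_giant_component).lower()}\n"
        )
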