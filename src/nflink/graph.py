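"""Undirected simple-graph container, edge-list I/O and topology statistics.

The :class:`Network` is the sole input object of the package: an ordered set
of opaque node labels plus a set of unordered edges.  Matrices derived from a
network (adjacency, Laplacians, feature matrices) always carry the node
ordering used for their rows and columns, so results are label-stable rather
than order-stable.  Node labels are opaque strings; numeric-looking labels
are never coerced.
"""

from __future__ import annotations

import io
import logging
import math
import os
from dataclasses import dataclass
from functools import cached_property
from typing import IO, Iterable, Union

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

Edge = tuple[str, str]

#: Line prefixes treated as comments in edge-list files.
COMMENT_PREFIXES = ("#", "%")


@dataclass(frozen=True)
class Network:
    """An undirected simple graph.

    Invariants: no self-loops, no duplicate edges ({u,v} and {v,u} are the
    same edge), every edge endpoint is a known node.  Nodes may be isolated.
    Edges are stored as lexicographically ordered label tuples, so edge-set
    equality is independent of node order.
    """

    nodes: tuple[str, ...]
    edges: frozenset[Edge]

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[object, object]],
        nodes: Iterable[object] = (),
    ) -> "Network":
        """Build a network from edge pairs (plus optional extra nodes).

        Duplicate edges are merged silently (set semantics); a self-loop is a
        contract violation and raises ``ValueError``.  Node order is
        first-appearance order: explicitly listed nodes first, then endpoints
        in the order encountered.
        """
        order: dict[str, int] = {}
        for v in nodes:
            order.setdefault(str(v), len(order))
        canon: set[Edge] = set()
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                raise ValueError(f"self-loop on node {u!r} is not allowed")
            order.setdefault(u, len(order))
            order.setdefault(v, len(order))
            canon.add((u, v) if u < v else (v, u))
        return cls(nodes=tuple(order), edges=frozenset(canon))

    # -- basic accessors -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @cached_property
    def index(self) -> dict[str, int]:
        """Node label -> row/column position."""
        return {v: i for i, v in enumerate(self.nodes)}

    def canonical_edge(self, u: object, v: object) -> Edge:
        """Lexicographically ordered tuple, independent of node order."""
        u, v = str(u), str(v)
        idx = self.index
        if u not in idx or v not in idx:
            raise KeyError(f"unknown node in pair ({u!r}, {v!r})")
        return (u, v) if u < v else (v, u)

    def has_edge(self, u: object, v: object) -> bool:
        return self.canonical_edge(u, v) in self.edges

    def edge_list(self) -> list[Edge]:
        """Edges in deterministic (node-order lexicographic) order."""
        idx = self.index
        return sorted(self.edges, key=lambda e: (idx[e[0]], idx[e[1]]))

    @cached_property
    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_nodes, dtype=np.int64)
        idx = self.index
        for u, v in self.edges:
            d[idx[u]] += 1
            d[idx[v]] += 1
        return d

    def replace_edges(self, edges: Iterable[tuple[object, object]]) -> "Network":
        """Same node universe, different edge set."""
        return Network.from_edges(edges, nodes=self.nodes)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class LabeledMatrix:
    """A square matrix together with the node ordering of its rows/columns."""

    values: np.ndarray
    ordering: tuple[str, ...]


@dataclass(frozen=True)
class TopologyStats:
    """The per-network summary statistics reported for benchmark corpora.

    ``clustering`` is the average local clustering coefficient (nodes of
    degree < 2 contribute 0); ``transitivity`` is the global triangle ratio,
    exposed as a secondary field.  ``heterogeneity`` is H = <k^2>/<k>^2, equal
    to 1 exactly on regular graphs and large on hub-dominated ones.
    Statistics that are undefined for the input (e.g. assortativity of a
    regular graph) are NaN.
    """

    n_nodes: int
    n_edges: int
    clustering: float
    assortativity: float
    mean_degree: float
    heterogeneity: float
    transitivity: float

    def as_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "clustering": self.clustering,
            "assortativity": self.assortativity,
            "mean_degree": self.mean_degree,
            "heterogeneity": self.heterogeneity,
            "transitivity": self.transitivity,
        }


# ---------------------------------------------------------------------------
# Edge-list I/O
# ---------------------------------------------------------------------------

Source = Union[str, os.PathLike, IO[str], Iterable[str]]


def read_edge_list(source: Source, comment_prefixes=COMMENT_PREFIXES) -> Network:
    """Parse a plain-text edge list into a :class:`Network`.

    One edge per line; the first two whitespace-separated tokens are the
    endpoints (extra tokens, e.g. weights, are ignored).  Lines starting with
    a comment prefix and blank lines are skipped.  Duplicate edges are
    merged, self-loops dropped and direction discarded, turning arbitrary
    input into an undirected simple graph; the number of merged/dropped lines
    is reported through logging.

    Raises ``ValueError`` naming the line number if a non-comment line has
    fewer than two tokens.
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source, "r", encoding="utf-8") as fh:
            return read_edge_list(fh, comment_prefixes)

    order: dict[str, int] = {}
    edges: set[Edge] = set()
    n_loops = n_dupes = 0
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith(tuple(comment_prefixes)):
            continue
        tokens = line.split()
        if len(tokens) < 2:
            raise ValueError(
                f"malformed edge-list line {lineno}: expected at least two "
                f"tokens, got {line!r}"
            )
        u, v = tokens[0], tokens[1]
        order.setdefault(u, len(order))
        if u == v:
            n_loops += 1
            continue
        order.setdefault(v, len(order))
        edge = (u, v) if u < v else (v, u)
        if edge in edges:
            n_dupes += 1
        else:
            edges.add(edge)
    if n_loops or n_dupes:
        logger.info(
            "read_edge_list: dropped %d self-loop(s), merged %d duplicate "
            "edge line(s)", n_loops, n_dupes,
        )
    return Network(nodes=tuple(order), edges=frozenset(edges))


def write_edge_list(net: Network, target: Union[str, os.PathLike, IO[str]]) -> None:
    """Write a network as plain text, one canonical edge per line."""
    if isinstance(target, (str, os.PathLike)):
        with open(target, "w", encoding="utf-8") as fh:
            write_edge_list(net, fh)
        return
    for u, v in net.edge_list():
        target.write(f"{u} {v}\n")


def edge_list_text(net: Network) -> str:
    buf = io.StringIO()
    write_edge_list(net, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------


def adjacency_matrix(net: Network) -> LabeledMatrix:
    """Dense symmetric 0/1 adjacency matrix A in the network's node order."""
    n = net.n_nodes
    a = np.zeros((n, n), dtype=float)
    idx = net.index
    for u, v in net.edges:
        i, j = idx[u], idx[v]
        a[i, j] = a[j, i] = 1.0
    return LabeledMatrix(values=a, ordering=net.nodes)


def laplacian(net: Network) -> LabeledMatrix:
    """Unnormalized Laplacian L = D - A (quadratic form sums (x_i - x_j)^2
    over edges; biased toward high-degree nodes)."""
    a = adjacency_matrix(net).values
    return LabeledMatrix(values=np.diag(a.sum(axis=1)) - a, ordering=net.nodes)


def normalized_laplacian(net: Network) -> LabeledMatrix:
    """Normalized Laplacian L~ = I - D^{-1/2} A D^{-1/2}.

    Rows and columns of degree-0 nodes are identically zero (including the
    diagonal): an isolated node contributes no dissimilarity and no frequency
    content, which keeps the spectrum inside [0, 2].
    """
    a = adjacency_matrix(net).values
    d = a.sum(axis=1)
    inv_sqrt = np.zeros_like(d)
    pos = d > 0
    inv_sqrt[pos] = 1.0 / np.sqrt(d[pos])
    lap = -inv_sqrt[:, None] * a * inv_sqrt[None, :]
    lap[np.diag_indices_from(lap)] = np.where(pos, 1.0, 0.0)
    return LabeledMatrix(values=lap, ordering=net.nodes)


# ---------------------------------------------------------------------------
# Topology statistics
# ---------------------------------------------------------------------------


def _degree_assortativity(net: Network) -> float:
    """Pearson correlation of endpoint degrees over edges counted in both
    orientations; NaN when undefined (no edges, or constant endpoint degree)."""
    if net.n_nodes < 2 or net.n_edges == 0:
        return math.nan
    idx = net.index
    deg = net.degrees
    xs, ys = [], []
    for u, v in net.edges:
        du, dv = deg[idx[u]], deg[idx[v]]
        xs.extend((du, dv))
        ys.extend((dv, du))
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if np.var(x) == 0 or np.var(y) == 0:
        return math.nan
    return float(np.corrcoef(x, y)[0, 1])


def topology_stats(net: Network) -> TopologyStats:
    """Summary statistics: counts, clustering, assortativity, mean degree and
    degree heterogeneity H = <k^2>/<k>^2."""
    n, m = net.n_nodes, net.n_edges
    if n == 0:
        return TopologyStats(0, 0, math.nan, math.nan, math.nan, math.nan, math.nan)
    g = net.to_networkx()
    clustering = float(nx.average_clustering(g))
    transitivity = float(nx.transitivity(g))
    deg = net.degrees.astype(float)
    mean_k = float(deg.mean())
    heterogeneity = float((deg**2).mean() / mean_k**2) if mean_k > 0 else math.nan
    return TopologyStats(
        n_nodes=n,
        n_edges=m,
        clustering=clustering,
        assortativity=_degree_assortativity(net),
        mean_degree=mean_k,
        heterogeneity=heterogeneity,
        transitivity=transitivity,
    )
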