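"""Synthetic network generators and the five-node worked example.

Everything the test-bench needs without downloads: Erdős–Rényi and
preferential-attachment random graphs, planted-partition graphs whose block
structure gives the low-frequency Laplacian eigenvectors a predictable
signal to recover, a noise-injection transform that rewires a fraction of
the edges, and the small five-node graph used throughout as a worked
example (its nodes 4 and 5 — and 2 and 3 — are topologically equivalent,
which is what motivates the A + I feature choice).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph import Network


def fig1_network() -> Network:
    """The five-node demonstration graph.

    Nodes 1..5 with edges 1-2, 1-3, 2-3, 2-4, 2-5, 3-4, 3-5, 4-5: the unique
    simple graph in which row 4 of A is [0,1,1,0,1], row 5 is [0,1,1,1,0],
    and rows 4 and 5 of A + I coincide.
    """
    edges = [(1, 2), (1, 3), (2, 3), (2, 4), (2, 5), (3, 4), (3, 5), (4, 5)]
    return Network.from_edges(edges, nodes=[1, 2, 3, 4, 5])


def _from_networkx(g: nx.Graph, n: int) -> Network:
    return Network.from_edges(g.edges(), nodes=range(n))


def erdos_renyi(n: int, p: float, seed: int | None = None) -> Network:
    """G(n, p): each of the n(n-1)/2 pairs linked independently with
    probability p."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    return _from_networkx(nx.gnp_random_graph(n, p, seed=seed), n)


def pref_attachment(n: int, m: int, seed: int | None = None) -> Network:
    """Preferential-attachment growth: each new node attaches m links to
    existing nodes proportionally to degree, starting from a complete seed
    core on m + 1 nodes (so |E| = C(m+1, 2) + (n - m - 1) * m)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 1 <= m < n:
        raise ValueError("m must satisfy 1 <= m < n")
    core = nx.complete_graph(m + 1)
    g = nx.barabasi_albert_graph(n, m, seed=seed, initial_graph=core)
    return _from_networkx(g, n)


def planted_partition(
    n: int, blocks: int, p_in: float, p_out: float, seed: int | None = None
) -> Network:
    """Planted-partition graph: ``blocks`` equal groups, within-block pairs
    linked with p_in, cross-block with p_out (p_in > p_out so the blocks are
    a real signal)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if blocks < 1 or n % blocks != 0:
        raise ValueError("blocks must divide n")
    if not (0 <= p_out <= 1 and 0 <= p_in <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if p_in <= p_out:
        raise ValueError("planted partition requires p_in > p_out")
    g = nx.planted_partition_graph(blocks, n // blocks, p_in, p_out, seed=seed)
    return _from_networkx(g, n)


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative recipe for a synthetic network (used by the CLI and for
    recording provenance in artifacts)."""

    family: str
    n: int = 0
    p: float = 0.0
    m: int = 1
    blocks: int = 1
    p_in: float = 0.0
    p_out: float = 0.0
    seed: int | None = None


def generate(spec: GeneratorSpec) -> Network:
    """Materialise a :class:`GeneratorSpec`; the same spec and seed always
    produce the identical graph."""
    if spec.family == "fig1":
        return fig1_network()
    if spec.family == "erdos_renyi":
        return erdos_renyi(spec.n, spec.p, seed=spec.seed)
    if spec.family == "pref_attachment":
        return pref_attachment(spec.n, spec.m, seed=spec.seed)
    if spec.family == "planted_partition":
        return planted_partition(
            spec.n, spec.blocks, spec.p_in, spec.p_out, seed=spec.seed
        )
    raise ValueError(f"unknown generator family {spec.family!r}")


def inject_noise(net: Network, fraction: float, seed: int | None = None) -> Network:
    """Rewire a fraction of the links: remove floor(fraction * |E|) randomly
    chosen edges and add the same number of randomly chosen non-edges.

    The edge count is preserved; the node universe is unchanged.  Raises if
    the graph is too dense to supply enough non-edges.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    edges = net.edge_list()
    n_swap = int(fraction * len(edges))
    if n_swap == 0:
        return net
    idx = net.index
    all_i, all_j = np.triu_indices(net.n_nodes, k=1)
    edge_set = {tuple(sorted((idx[u], idx[v]))) for u, v in edges}
    non_edges = [
        (i, j) for i, j in zip(all_i.tolist(), all_j.tolist())
        if (i, j) not in edge_set
    ]
    if len(non_edges) < n_swap:
        raise ValueError(
            f"cannot add {n_swap} edges: only {len(non_edges)} non-edges available"
        )
    rng = np.random.default_rng(seed)
    removed = rng.choice(len(edges), size=n_swap, replace=False)
    added = rng.choice(len(non_edges), size=n_swap, replace=False)
    kept = [e for k, e in enumerate(edges) if k not in set(removed.tolist())]
    nodes = net.nodes
    new_edges = kept + [(nodes[non_edges[k][0]], nodes[non_edges[k][1]])
                        for k in added.tolist()]
    return Network.from_edges(new_edges, nodes=nodes)
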