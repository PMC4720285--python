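"""Independent brute-force reference implementations used as test oracles.

Everything here is written in the most literal way possible (explicit loops,
explicit matrix assembly, numpy.linalg rather than the package's scipy
paths) and deliberately shares no code with the package under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def neighbours(net) -> dict[str, set[str]]:
    nbrs: dict[str, set[str]] = {v: set() for v in net.nodes}
    for u, v in net.edges:
        nbrs[u].add(v)
        nbrs[v].add(u)
    return nbrs


def non_edges(net) -> list[tuple[str, str]]:
    out = []
    nodes = net.nodes
    linked = {frozenset(e) for e in net.edges}
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if frozenset((nodes[i], nodes[j])) not in linked:
                out.append((nodes[i], nodes[j]))
    return out


# -- similarity indices ------------------------------------------------------


def cn(net, x, y) -> float:
    nbrs = neighbours(net)
    return float(len(nbrs[x] & nbrs[y]))


def aa(net, x, y) -> float:
    nbrs = neighbours(net)
    return float(sum(1.0 / math.log(len(nbrs[z])) for z in nbrs[x] & nbrs[y]))


def ra(net, x, y) -> float:
    nbrs = neighbours(net)
    return float(sum(1.0 / len(nbrs[z]) for z in nbrs[x] & nbrs[y]))


def pa(net, x, y) -> float:
    nbrs = neighbours(net)
    return float(len(nbrs[x]) * len(nbrs[y]))


def adjacency(net) -> np.ndarray:
    n = len(net.nodes)
    pos = {v: i for i, v in enumerate(net.nodes)}
    a = np.zeros((n, n))
    for u, v in net.edges:
        a[pos[u], pos[v]] = 1.0
        a[pos[v], pos[u]] = 1.0
    return a


def lp(net, x, y, epsilon) -> float:
    a = adjacency(net)
    pos = {v: i for i, v in enumerate(net.nodes)}
    a2 = a @ a
    a3 = a2 @ a
    return float(a2[pos[x], pos[y]] + epsilon * a3[pos[x], pos[y]])


def katz_closed(net, x, y, beta) -> float:
    a = adjacency(net)
    pos = {v: i for i, v in enumerate(net.nodes)}
    s = np.linalg.inv(np.eye(len(a)) - beta * a) - np.eye(len(a))
    return float(s[pos[x], pos[y]])


def katz_truncated(net, x, y, beta, order) -> float:
    a = adjacency(net)
    pos = {v: i for i, v in enumerate(net.nodes)}
    # literal series: sum_k beta^k A^k
    total = np.zeros_like(a)
    for k in range(1, order + 1):
        total = total + beta**k * np.linalg.matrix_power(a, k)
    return float(total[pos[x], pos[y]])


# -- spectral noise filtering ------------------------------------------------


def normalized_laplacian(net) -> np.ndarray:
    a = adjacency(net)
    n = len(a)
    d = a.sum(axis=1)
    lap = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j and d[i] > 0:
                lap[i, j] = 1.0
            elif a[i, j] and d[i] > 0 and d[j] > 0:
                lap[i, j] = -1.0 / math.sqrt(d[i] * d[j])
    return lap


def nf_matrix(net, t, tol=1e-9) -> np.ndarray:
    """Literal S* = (V_t V_t^T (A+I) + transpose)/2, degenerate eigenspaces
    at the cutoff retained in full."""
    a = adjacency(net)
    n = len(a)
    w, v = np.linalg.eigh(normalized_laplacian(net))
    while t < n and w[t] - w[t - 1] < tol:
        t += 1
    x = a + np.eye(n)
    if t >= n:
        return x
    vt = v[:, :t]
    s = vt @ vt.T @ x
    return (s + s.T) / 2.0


def quadratic_form_edge_sum(net, x) -> float:
    """x^T L~ x computed as the edge sum of (x_i/sqrt(d_i) - x_j/sqrt(d_j))^2."""
    pos = {v: i for i, v in enumerate(net.nodes)}
    d = adjacency(net).sum(axis=1)
    total = 0.0
    for u, v in net.edges:
        i, j = pos[u], pos[v]
        total += (x[i] / math.sqrt(d[i]) - x[j] / math.sqrt(d[j])) ** 2
    return total


# -- metrics -----------------------------------------------------------------


def auc_pairwise(pos, neg) -> float:
    """All-pairs comparison loop, ties counted one half."""
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def precision_enumerated(pos, neg, L) -> float:
    """Expected precision@L, averaging over every ordering of tied items.

    Items are labelled probe/non-probe; all permutations of items within
    each tie group are enumerated (feasible only for tiny inputs).
    """
    items = [(s, True) for s in pos] + [(s, False) for s in neg]
    groups: dict[float, list[bool]] = {}
    for s, is_pos in items:
        groups.setdefault(s, []).append(is_pos)
    total = 0.0
    count = 0
    per_group = [
        list(set(itertools.permutations(flags))) for _, flags in
        sorted(groups.items(), key=lambda kv: -kv[0])
    ]
    for combo in itertools.product(*per_group):
        ranking = [flag for group in combo for flag in group]
        total += sum(ranking[:L]) / L
        count += 1
    return total / count
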