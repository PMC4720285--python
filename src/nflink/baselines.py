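"""Classical similarity indices for link prediction.

Six comparison predictors, each scoring every non-observed pair of the
training graph: Common Neighbours (CN), Adamic-Adar (AA), Resource
Allocation (RA), Preferential Attachment (PA), Local Path (LP) and Katz.
The first four use local information, LP is quasi-local (paths up to length
3), Katz is global (all path lengths, exponentially damped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .graph import Network, adjacency_matrix
from .scoring import ScoreTable, table_from_matrix


@dataclass(frozen=True)
class IndexParams:
    """Parameters of the parameter-dependent indices.

    ``epsilon`` damps the length-3 path term of LP; ``beta`` damps Katz path
    counts by length (``None`` means 0.5 / lambda_max of the training
    adjacency).  Katz has a closed form (I - beta*A)^{-1} - I requiring
    beta < 1/lambda_max, or a truncated series capped at
    ``truncation_order``.
    """

    epsilon: float = 1e-3
    beta: float | None = None
    katz_mode: str = "closed_form"
    truncation_order: int = 30

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.beta is not None and self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.katz_mode not in ("closed_form", "truncated"):
            raise ValueError("katz_mode must be 'closed_form' or 'truncated'")
        if self.truncation_order < 1:
            raise ValueError("truncation_order must be >= 1")


def cn_scores(net: Network) -> ScoreTable:
    """Common Neighbours: s_xy = |Gamma(x) n Gamma(y)| = (A^2)_xy."""
    a = adjacency_matrix(net).values
    return table_from_matrix(net, a @ a, method="CN")


def aa_scores(net: Network) -> ScoreTable:
    """Adamic-Adar: sum over common neighbours z of 1/ln d_z (natural log;
    a common neighbour in a simple graph always has degree >= 2)."""
    a = adjacency_matrix(net).values
    d = a.sum(axis=1)
    w = np.zeros_like(d)
    mask = d > 1
    w[mask] = 1.0 / np.log(d[mask])
    return table_from_matrix(net, (a * w) @ a, method="AA")


def ra_scores(net: Network) -> ScoreTable:
    """Resource Allocation: sum over common neighbours z of 1/d_z."""
    a = adjacency_matrix(net).values
    d = a.sum(axis=1)
    w = np.zeros_like(d)
    mask = d > 0
    w[mask] = 1.0 / d[mask]
    return table_from_matrix(net, (a * w) @ a, method="RA")


def pa_scores(net: Network) -> ScoreTable:
    """Preferential Attachment: s_xy = d_x * d_y."""
    d = adjacency_matrix(net).values.sum(axis=1)
    return table_from_matrix(net, np.outer(d, d), method="PA")


def lp_scores(net: Network, params: IndexParams = IndexParams()) -> ScoreTable:
    """Local Path: s = A^2 + epsilon * A^3 (paths of length 2 and 3)."""
    a = adjacency_matrix(net).values
    a2 = a @ a
    s = a2 + params.epsilon * (a2 @ a)
    return table_from_matrix(net, s, method="LP", params={"epsilon": params.epsilon})


def katz_scores(net: Network, params: IndexParams = IndexParams()) -> ScoreTable:
    """Katz: damped count of paths of every length between x and y.

    Closed form S = (I - beta*A)^{-1} - I, valid for beta < 1/lambda_max(A);
    truncated mode sums beta^k A^k for k = 1..truncation_order and converges
    to the closed form geometrically.
    """
    a = adjacency_matrix(net).values
    n = net.n_nodes
    lam_max = float(scipy.linalg.eigvalsh(a)[-1]) if n else 0.0
    beta = params.beta
    if beta is None:
        beta = 0.5 / lam_max if lam_max > 0 else 0.0
    meta = {"beta": beta, "katz_mode": params.katz_mode}
    if params.katz_mode == "closed_form":
        if lam_max > 0 and beta >= 1.0 / lam_max:
            raise ValueError(
                f"Katz series diverges: beta={beta} >= 1/lambda_max = "
                f"{1.0 / lam_max} (lambda_max = {lam_max})"
            )
        s = scipy.linalg.inv(np.eye(n) - beta * a) - np.eye(n)
    else:
        meta["truncation_order"] = params.truncation_order
        s = np.zeros_like(a)
        term = np.eye(n)
        for _ in range(params.truncation_order):
            term = beta * (term @ a)
            s += term
    return table_from_matrix(net, s, method="Katz", params=meta)
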