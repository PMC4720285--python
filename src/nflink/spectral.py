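"""Noise-filtering (NF) link prediction via normalized-Laplacian filtering.

The method treats the observed connections of a network as noisy
information.  Each node's feature vector is its row of X = A + I (adding the
identity makes topologically equivalent linked nodes share identical
features).  The dissimilarity carried by feature x is the quadratic form
x^T L~ x of the normalized Laplacian; eigenvectors of L~ with small
eigenvalues vary slowly across links ("low frequency") while those with
large eigenvalues capture links between dissimilar nodes, interpreted as
noise.  Projecting the features onto the t lowest-frequency eigenvectors,

    S_hat = V_t V_t^T (A + I),

and symmetrising, S* = (S_hat + S_hat^T)/2, yields similarity scores for
every non-observed pair.  The cutoff t is selected by K-fold cross-validation
on the training links.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

from . import metrics
from .graph import LabeledMatrix, Network, adjacency_matrix, normalized_laplacian
from .scoring import ScoreTable, non_observed_pairs, table_from_matrix

#: Eigenvalue gaps below this are treated as degenerate (see
#: :func:`effective_cutoff`).
DEGENERACY_TOL = 1e-9

#: Above this size the full dense eigendecomposition is replaced by a partial
#: one (only the needed smallest eigenpairs); the CV grid is capped at 125,
#: so a partial spectrum suffices at scale.
DENSE_LIMIT = 5000


@dataclass(frozen=True)
class SpectralBasis:
    """Ascending eigendecomposition of a symmetric matrix (typically L~).

    Column l of ``eigenvectors`` pairs with ``eigenvalues[l]``; the basis is
    orthonormal.  The basis may be partial (k < n columns) for large graphs.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    ordering: tuple[str, ...]


def feature_matrix(net: Network) -> LabeledMatrix:
    """Node features X = A + I: row i flags the nodes within distance 1 of
    node i (itself included), so linked nodes with identical neighbourhoods
    get identical feature rows."""
    a = adjacency_matrix(net).values
    return LabeledMatrix(values=a + np.eye(net.n_nodes), ordering=net.nodes)


def dissimilarity(feature: np.ndarray, lap: LabeledMatrix) -> float:
    """Quadratic form x^T L~ x: how strongly a feature differs across linked
    nodes, degree-normalized.  Non-negative up to rounding."""
    x = np.asarray(feature, dtype=float)
    n = lap.values.shape[0]
    if x.shape != (n,):
        raise ValueError(f"feature has shape {x.shape}, expected ({n},)")
    return float(x @ lap.values @ x)


def spectral_basis(lap: LabeledMatrix, n_components: int | None = None) -> SpectralBasis:
    """Eigendecomposition of a symmetric matrix, eigenvalues ascending.

    Sign convention: the first component of each eigenvector with magnitude
    above 1e-12 is made positive, so runs are reproducible across linear
    algebra backends.  For matrices larger than ``DENSE_LIMIT`` only the
    ``n_components`` smallest eigenpairs are computed.
    """
    m = np.asarray(lap.values, dtype=float)
    if m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(m, m.T, atol=1e-9, rtol=0.0):
        raise ValueError("matrix must be symmetric within 1e-9")
    n = m.shape[0]
    if n <= DENSE_LIMIT or n_components is None or n_components >= n:
        vals, vecs = scipy.linalg.eigh((m + m.T) / 2.0)
        if n_components is not None and n_components < n:
            vals, vecs = vals[:n_components], vecs[:, :n_components]
    else:
        vals, vecs = scipy.sparse.linalg.eigsh(
            scipy.sparse.csr_matrix(m), k=n_components, which="SA"
        )
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
    for col in range(vecs.shape[1]):
        nz = np.flatnonzero(np.abs(vecs[:, col]) > 1e-12)
        if nz.size and vecs[nz[0], col] < 0:
            vecs[:, col] = -vecs[:, col]
    return SpectralBasis(eigenvalues=vals, eigenvectors=vecs, ordering=lap.ordering)


def effective_cutoff(
    eigenvalues: np.ndarray, t: int, tol: float = DEGENERACY_TOL
) -> tuple[int, float]:
    """Enlarge t to cover a degenerate eigenspace at the cutoff.

    If the gap between the last retained and the first discarded eigenvalue
    is below ``tol``, the whole tied eigenspace is retained, which makes the
    projector independent of the arbitrary basis chosen inside the eigenspace.
    Returns (effective_t, gap_at_cutoff); the gap is +inf when everything is
    retained.
    """
    n = len(eigenvalues)
    if not 1 <= t <= n:
        raise ValueError(f"cutoff t={t} out of range [1, {n}]")
    while t < n and eigenvalues[t] - eigenvalues[t - 1] < tol:
        t += 1
    gap = float(eigenvalues[t] - eigenvalues[t - 1]) if t < n else float("inf")
    return t, gap


def nf_score_matrix(
    net: Network,
    t: int,
    feature: np.ndarray | None = None,
    basis: SpectralBasis | None = None,
) -> tuple[np.ndarray, int, float]:
    """Symmetrised noise-filtered score matrix S* = (S_hat + S_hat^T)/2.

    Returns (S*, effective_t, eigen_gap).  ``feature`` defaults to A + I;
    a user feature matrix of matching shape may be substituted.  When the
    (possibly enlarged) cutoff retains the whole basis, the projector is the
    identity and X is returned unchanged.
    """
    n = net.n_nodes
    if not 1 <= t <= n:
        raise ValueError(f"cutoff t={t} out of range [1, {n}]")
    x = feature_matrix(net).values if feature is None else np.asarray(feature, float)
    if x.shape != (n, n):
        raise ValueError(f"feature matrix has shape {x.shape}, expected ({n}, {n})")
    if basis is None:
        basis = spectral_basis(normalized_laplacian(net))
    eff_t, gap = effective_cutoff(basis.eigenvalues, t)
    if eff_t >= n:
        return x.copy(), eff_t, gap
    vt = basis.eigenvectors[:, :eff_t]
    s_hat = vt @ (vt.T @ x)
    return (s_hat + s_hat.T) / 2.0, eff_t, gap


def nf_scores(net: Network, t: int, feature: np.ndarray | None = None) -> ScoreTable:
    """Noise-filtered similarity scores for every non-observed pair.

    ``t`` counts the retained low-frequency eigenvectors of the training
    graph's normalized Laplacian (1 <= t <= n); a degenerate eigenvalue at
    the cutoff enlarges it to the full eigenspace, recorded in the params.
    """
    s_sym, eff_t, gap = nf_score_matrix(net, t, feature=feature)
    return table_from_matrix(
        net, s_sym, method="NF",
        params={"t": int(t), "effective_t": int(eff_t), "eigen_gap": gap},
    )


@dataclass(frozen=True)
class CutoffSelection:
    """Result of K-fold cross-validated selection of the NF cutoff t."""

    chosen_t: int
    grid: tuple[int, ...]
    cv_scores: np.ndarray
    K: int
    repeats: int
    metric: str
    seed: int | None

    def as_dict(self) -> dict:
        return {
            "chosen_t": self.chosen_t,
            "grid": list(self.grid),
            "cv_scores": [float(s) for s in self.cv_scores],
            "K": self.K,
            "repeats": self.repeats,
            "metric": self.metric,
            "seed": self.seed,
        }


def default_grid(n: int) -> list[int]:
    """Candidate cutoffs 1..min(125, n-1)."""
    return list(range(1, min(125, n - 1) + 1))


def select_t(
    net: Network,
    grid: list[int] | None = None,
    K: int = 10,
    repeats: int = 5,
    metric: str = "auc",
    seed: int | None = None,
) -> CutoffSelection:
    """Pick the NF cutoff by repeated K-fold cross-validation on the
    training links.

    The observed links are partitioned into K folds; each fold in turn is
    held out as validation probe links while the remaining folds form the
    known graph.  For every candidate t the chosen metric (AUC, or
    precision@|fold|) is computed against the non-existent pairs of the full
    observed graph, averaged over K folds x repeats; the maximiser wins and
    ties go to the smallest t.
    """
    n = net.n_nodes
    m = net.n_edges
    if grid is None:
        grid = default_grid(n)
    grid = sorted(int(t) for t in grid)
    if not grid:
        raise ValueError("candidate grid is empty")
    if any(t < 1 or t > n for t in grid):
        raise ValueError(f"grid values must lie in [1, {n}]")
    if K < 2:
        raise ValueError("K must be at least 2")
    if m < K:
        raise ValueError(f"need at least K={K} training edges, have {m}")
    if metric not in ("auc", "precision"):
        raise ValueError("metric must be 'auc' or 'precision'")

    rng = np.random.default_rng(seed)
    edges = net.edge_list()
    idx = net.index
    edge_rows = np.array([[idx[u], idx[v]] for u, v in edges])
    # non-existent pairs of the full observed graph (never validation links)
    _, neg_i, neg_j = non_observed_pairs(net)

    totals = np.zeros(len(grid))
    for _ in range(repeats):
        perm = rng.permutation(m)
        folds = np.array_split(perm, K)
        for fold in folds:
            if fold.size == 0:
                raise ValueError("a fold has no validation edges; reduce K")
            keep = np.ones(m, dtype=bool)
            keep[fold] = False
            sub = net.replace_edges(edges[i] for i in np.flatnonzero(keep))
            basis = spectral_basis(normalized_laplacian(sub))
            x = feature_matrix(sub).values
            eff = {}
            for gi, t in enumerate(grid):
                eff_t, _ = effective_cutoff(basis.eigenvalues, t)
                eff.setdefault(eff_t, []).append(gi)
            pos_i, pos_j = edge_rows[fold, 0], edge_rows[fold, 1]
            vecs = basis.eigenvectors
            proj = vecs.T @ x

            def record(level: int, s_use: np.ndarray) -> None:
                pos = s_use[pos_i, pos_j]
                neg = s_use[neg_i, neg_j]
                if metric == "auc":
                    val = metrics.exact_auc(pos, neg)
                else:
                    val, _ = metrics.precision_fraction(pos, neg, L=len(pos))
                for gi in eff[level]:
                    totals[gi] += val

            # accumulate the projection one eigenvector at a time so every
            # cutoff in the grid reuses the same eigendecomposition
            s = np.zeros_like(x)
            partial_levels = [l for l in eff if l < n]
            for level in range(1, max(partial_levels, default=0) + 1):
                s += np.outer(vecs[:, level - 1], proj[level - 1])
                if level in eff:
                    record(level, (s + s.T) / 2.0)
            if n in eff:
                record(n, x)  # full basis: the projector is the identity
    cv_scores = totals / (repeats * K)
    chosen = grid[int(np.argmax(cv_scores))]  # argmax returns first max: smallest t
    return CutoffSelection(
        chosen_t=chosen,
        grid=tuple(grid),
        cv_scores=cv_scores,
        K=K,
        repeats=repeats,
        metric=metric,
        seed=seed,
    )
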