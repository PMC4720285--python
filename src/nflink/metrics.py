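"""Rank-metric kernels shared by the evaluation API and cross-validation.

These operate on raw score arrays: ``pos`` holds the scores of held-out
(probe) links, ``neg`` the scores of truly non-existent links.
"""

from __future__ import annotations

import numpy as np


def exact_auc_counts(pos: np.ndarray, neg: np.ndarray) -> tuple[int, int, int]:
    """Exact comparison tallies over all |pos|*|neg| pairs.

    Returns (n, n_higher, n_tied): total comparisons, comparisons where the
    probe link outscores the non-existent link, and ties.
    """
    pos = np.asarray(pos, dtype=float)
    neg_sorted = np.sort(np.asarray(neg, dtype=float))
    lo = np.searchsorted(neg_sorted, pos, side="left")
    hi = np.searchsorted(neg_sorted, pos, side="right")
    n_higher = int(lo.sum())
    n_tied = int((hi - lo).sum())
    return len(pos) * len(neg_sorted), n_higher, n_tied


def exact_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Probability a random probe link outscores a random non-existent link,
    ties counted one half."""
    n, n_higher, n_tied = exact_auc_counts(pos, neg)
    return (n_higher + 0.5 * n_tied) / n


def sampled_auc_counts(
    pos: np.ndarray,
    neg: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
) -> tuple[int, int, int]:
    """Monte-Carlo tallies from ``n_samples`` independent (probe,
    non-existent) draws with replacement."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    ps = pos[rng.integers(0, len(pos), size=n_samples)]
    ns = neg[rng.integers(0, len(neg), size=n_samples)]
    n_higher = int(np.count_nonzero(ps > ns))
    n_tied = int(np.count_nonzero(ps == ns))
    return n_samples, n_higher, n_tied


def precision_fraction(pos: np.ndarray, neg: np.ndarray, L: int) -> tuple[float, float]:
    """Precision@L with fractional tie credit.

    Ranks all scores descending and counts probe links among the top L.  A
    tie group straddling rank L receives its expected share under a uniformly
    random tie order, so the result is seed-independent given the scores.
    Returns (precision, L_correct).
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    alls = np.concatenate([pos, neg])
    if not 1 <= L <= len(alls):
        raise ValueError(f"L={L} out of range for {len(alls)} scored pairs")
    thr = np.partition(alls, len(alls) - L)[len(alls) - L]
    n_above = int(np.count_nonzero(alls > thr))
    pos_above = int(np.count_nonzero(pos > thr))
    tie_total = int(np.count_nonzero(alls == thr))
    tie_pos = int(np.count_nonzero(pos == thr))
    slots = L - n_above
    l_correct = pos_above + slots * tie_pos / tie_total
    return l_correct / L, l_correct
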