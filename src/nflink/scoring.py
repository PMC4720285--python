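"""Score tables: one similarity score per non-observed node pair.

Every predictor in the package returns a :class:`ScoreTable` covering exactly
the unordered pairs of distinct nodes that are NOT linked in the (training)
graph — the union of the held-out probe links and the truly non-existent
links.  Scores are symmetric in the pair argument and always finite.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from functools import cached_property
from typing import IO, Union

import numpy as np
import pandas as pd

from .graph import Edge, Network, adjacency_matrix


def non_observed_pairs(net: Network) -> tuple[list[Edge], np.ndarray, np.ndarray]:
    """All unordered pairs of distinct nodes absent from the edge set.

    Returns the pairs (canonical label tuples) together with the row/column
    index arrays locating them in any matrix using the network's ordering.
    """
    n = net.n_nodes
    a = adjacency_matrix(net).values
    iu, ju = np.triu_indices(n, k=1)
    mask = a[iu, ju] == 0
    iu, ju = iu[mask], ju[mask]
    nodes = net.nodes
    pairs = [(nodes[i], nodes[j]) for i, j in zip(iu, ju)]
    return pairs, iu, ju


@dataclass
class ScoreTable:
    """Scores over the non-observed pairs of a training graph.

    ``method`` identifies the predictor (CN, AA, RA, PA, LP, Katz, NF) and
    ``params`` records its parameter values so any table is reproducible
    from its own metadata.
    """

    pairs: tuple[Edge, ...]
    scores: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.pairs) != len(self.scores):
            raise ValueError("pairs and scores length mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    @cached_property
    def _lookup(self) -> dict[frozenset, float]:
        return {frozenset(p): s for p, s in zip(self.pairs, self.scores)}

    def score(self, u: object, v: object) -> float:
        """Score of an unordered pair; symmetric in its arguments."""
        key = frozenset((str(u), str(v)))
        if key not in self._lookup:
            raise KeyError(f"pair ({u!r}, {v!r}) is not a non-observed pair")
        return self._lookup[key]

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_u": [p[0] for p in self.pairs],
                "node_v": [p[1] for p in self.pairs],
                "score": self.scores,
                "method": self.method,
            }
        )

    def write_csv(
        self,
        path: Union[str, os.PathLike, IO[str]],
        sidecar: Union[str, os.PathLike, None] = None,
    ) -> None:
        """Write the table as CSV; optionally a JSON sidecar with the
        method's parameter record."""
        self.to_frame().to_csv(path, index=False)
        if sidecar is not None:
            with open(sidecar, "w", encoding="utf-8") as fh:
                json.dump({"method": self.method, "params": self.params}, fh, indent=2)
                fh.write("\n")


def table_from_matrix(
    net: Network,
    values: np.ndarray,
    method: str,
    params: dict | None = None,
) -> ScoreTable:
    """Extract the non-observed-pair entries of a symmetric score matrix."""
    pairs, iu, ju = non_observed_pairs(net)
    return ScoreTable(
        pairs=tuple(pairs),
        scores=values[iu, ju],
        method=method,
        params=dict(params or {}),
    )
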