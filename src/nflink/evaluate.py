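"""Train/probe splitting, AUC and precision metrics, and repeated-run
benchmarking.

The evaluation protocol hides a random fraction of the observed links (the
probe set E^P), hands the rest (the training set E^T) to a predictor, and
asks how well the predictor's scores separate the hidden links from the
truly non-existent pairs.  AUC is the probability that a random probe link
outscores a random non-existent link (ties counted one half); precision@L is
the fraction of probe links among the top-L ranked non-observed pairs, with
L defaulting to |E^P|.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Callable, Iterable, Sequence, Union

import numpy as np
import pandas as pd

from . import baselines, metrics, spectral
from .baselines import IndexParams
from .graph import Edge, Network
from .scoring import ScoreTable


@dataclass(frozen=True)
class EdgeSplit:
    """Disjoint partition of the observed links into training and probe sets.

    The training network keeps the full node universe, so probe links whose
    endpoints become isolated in the training graph are still scoreable.
    """

    nodes: tuple[str, ...]
    training: frozenset[Edge]
    probe: frozenset[Edge]
    fraction: float
    seed: int | None

    @cached_property
    def training_network(self) -> Network:
        return Network.from_edges(self.training, nodes=self.nodes)


@dataclass(frozen=True)
class EvaluationResult:
    """Outcome of an AUC and/or precision evaluation.

    ``n_comparisons``, ``n_higher`` and ``n_tied`` are the comparison
    tallies behind the AUC (total comparisons, probe-outscores-nonexistent,
    and ties); ``L_correct`` counts probe links among the top L (possibly
    fractional under ties at the boundary).
    """

    auc: float | None = None
    n_comparisons: int | None = None
    n_higher: int | None = None
    n_tied: int | None = None
    mode: str | None = None
    precision: float | None = None
    L: int | None = None
    L_correct: float | None = None


def split_edges(net: Network, f: float, seed: int | None = None) -> EdgeSplit:
    """Randomly divide the observed links into training (fraction f) and
    probe sets, uniformly without replacement.

    |E^T| = round(f * |E|); the same seed always yields the same split.
    """
    if not 0 < f <= 1:
        raise ValueError(f"training fraction f={f} must lie in (0, 1]")
    if net.n_edges < 1:
        raise ValueError("cannot split a network with no edges")
    edges = net.edge_list()
    m = len(edges)
    n_train = int(round(f * m))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    training = frozenset(edges[i] for i in perm[:n_train])
    probe = frozenset(edges[i] for i in perm[n_train:])
    return EdgeSplit(
        nodes=net.nodes, training=training, probe=probe, fraction=f, seed=seed
    )


def _pos_neg_scores(
    scores: ScoreTable, probe: Iterable[Edge]
) -> tuple[np.ndarray, np.ndarray]:
    probe_keys = {frozenset(p) for p in probe}
    missing = probe_keys - {frozenset(p) for p in scores.pairs}
    if missing:
        raise ValueError(
            f"{len(missing)} probe pair(s) are not covered by the score table"
        )
    in_probe = np.array([frozenset(p) in probe_keys for p in scores.pairs])
    return scores.scores[in_probe], scores.scores[~in_probe]


def auc(
    scores: ScoreTable,
    split: EdgeSplit,
    mode: str = "sampled",
    n_samples: int = 100_000,
    seed: int | None = None,
) -> EvaluationResult:
    """AUC of a score table against a train/probe split.

    ``sampled`` draws ``n_samples`` independent (probe, non-existent) score
    pairs and returns (n' + 0.5*n'')/n; ``exact`` computes the same
    expectation over all |E^P| x |U - E| comparisons by rank statistics.
    """
    if mode not in ("exact", "sampled"):
        raise ValueError("mode must be 'exact' or 'sampled'")
    pos, neg = _pos_neg_scores(scores, split.probe)
    if len(pos) == 0:
        raise ValueError("probe set is empty; nothing to evaluate")
    if len(neg) == 0:
        raise ValueError("no non-existent pairs; nothing to compare against")
    if mode == "exact":
        n, n_higher, n_tied = metrics.exact_auc_counts(pos, neg)
    else:
        rng = np.random.default_rng(seed)
        n, n_higher, n_tied = metrics.sampled_auc_counts(pos, neg, n_samples, rng)
    return EvaluationResult(
        auc=(n_higher + 0.5 * n_tied) / n,
        n_comparisons=n,
        n_higher=n_higher,
        n_tied=n_tied,
        mode=mode,
    )


def precision_at_L(
    scores: ScoreTable,
    probe: Iterable[Edge],
    L: int | None = None,
) -> EvaluationResult:
    """Precision@L: probe links among the top-L ranked non-observed pairs.

    L defaults to the probe-set size.  Ties straddling rank L get fractional
    credit (the expected count under a uniformly random tie order), so the
    result is seed-independent given the scores.
    """
    probe = list(probe)
    if L is None:
        L = len(probe)
    if L < 1:
        raise ValueError("L must be >= 1")
    pos, neg = _pos_neg_scores(scores, probe)
    precision, l_correct = metrics.precision_fraction(pos, neg, L)
    return EvaluationResult(precision=precision, L=L, L_correct=l_correct)


# ---------------------------------------------------------------------------
# Repeated-run benchmarking
# ---------------------------------------------------------------------------

#: Probe-fraction sweep used in training-fraction robustness plots.
DEFAULT_FRACTIONS = (0.5, 0.6, 0.7, 0.8, 0.9)

Scorer = Callable[[Network], ScoreTable]

MethodSpec = Union[str, tuple[str, dict]]


def _resolve_method(spec: MethodSpec) -> tuple[str, dict]:
    if isinstance(spec, str):
        return spec, {}
    name, params = spec
    return name, dict(params)


def make_scorer(
    name: str,
    params: dict,
    net: Network,
    seed: int | None = None,
) -> tuple[Scorer, dict]:
    """Build a training-graph -> ScoreTable callable for a named method.

    Parameter-bearing methods are configured once here and then held fixed
    across all benchmark runs.  For NF, a missing ``t`` triggers one
    cross-validated selection on the full observed network (``cv`` options:
    grid, K, repeats, metric).
    """
    name_l = name.lower()
    if name_l == "cn":
        return baselines.cn_scores, {}
    if name_l == "aa":
        return baselines.aa_scores, {}
    if name_l == "ra":
        return baselines.ra_scores, {}
    if name_l == "pa":
        return baselines.pa_scores, {}
    if name_l == "lp":
        ip = IndexParams(epsilon=params.get("epsilon", 1e-3))
        return (lambda g: baselines.lp_scores(g, ip)), {"epsilon": ip.epsilon}
    if name_l == "katz":
        ip = IndexParams(
            beta=params.get("beta"),
            katz_mode=params.get("katz_mode", "closed_form"),
            truncation_order=params.get("truncation_order", 30),
        )
        resolved = {"beta": ip.beta, "katz_mode": ip.katz_mode}
        return (lambda g: baselines.katz_scores(g, ip)), resolved
    if name_l == "nf":
        t = params.get("t")
        if t is None:
            cv = params.get("cv", {})
            selection = spectral.select_t(
                net,
                grid=cv.get("grid"),
                K=cv.get("K", 10),
                repeats=cv.get("repeats", 5),
                metric=cv.get("metric", "auc"),
                seed=seed,
            )
            t = selection.chosen_t
        t = int(t)
        return (lambda g: spectral.nf_scores(g, t)), {"t": t}
    raise ValueError(f"unknown method {name!r}")


@dataclass
class BenchmarkReport:
    """Mean and standard deviation of AUC and precision per (method, f)
    cell over independent train/probe splits.

    ``frame`` is long-format (network, method, f, metric, mean, sd, runs);
    ``raw`` holds the per-run values for auditing.  Standard deviations are
    population (ddof=0) so a single run reports sd = 0.
    """

    frame: pd.DataFrame
    raw: pd.DataFrame
    runs: int
    seed: int | None
    config: dict = field(default_factory=dict)

    def cell(self, method: str, f: float, metric: str) -> tuple[float, float]:
        sel = self.frame[
            (self.frame["method"] == method)
            & (np.isclose(self.frame["f"], f))
            & (self.frame["metric"] == metric)
        ]
        if sel.empty:
            raise KeyError(f"no cell for ({method}, {f}, {metric})")
        row = sel.iloc[0]
        return float(row["mean"]), float(row["sd"])

    def write_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def as_dict(self) -> dict:
        return {
            "runs": self.runs,
            "seed": self.seed,
            "config": self.config,
            "cells": self.frame.to_dict(orient="records"),
        }


def run_benchmark(
    net: Network,
    methods: Sequence[MethodSpec],
    fractions: Sequence[float] = (0.9,),
    runs: int = 100,
    seed: int | None = None,
    auc_mode: str = "exact",
    n_samples: int = 100_000,
    network_name: str = "network",
) -> BenchmarkReport:
    """Benchmark predictors over repeated independent train/probe splits.

    For every run an independent split is drawn from a seeded stream, each
    method is fitted on the training graph, and both AUC and precision@|E^P|
    are recorded; means and standard deviations per (method, f) cell are
    reported.  Method parameters (epsilon, beta, the NF cutoff t) are
    resolved once up front and held fixed across runs and fractions.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    root = np.random.SeedSequence(seed)
    scorer_seed, run_seed = root.spawn(2)
    scorer_rng = np.random.default_rng(scorer_seed)

    resolved: list[tuple[str, Scorer, dict]] = []
    for spec in methods:
        name, params = _resolve_method(spec)
        scorer, resolved_params = make_scorer(
            name, params, net, seed=int(scorer_rng.integers(2**31))
        )
        resolved.append((name, scorer, resolved_params))

    rows = []
    child_seeds = iter(run_seed.spawn(len(fractions) * runs * 2))
    for f in fractions:
        for run in range(runs):
            split_s = int(np.random.default_rng(next(child_seeds)).integers(2**31))
            auc_s = int(np.random.default_rng(next(child_seeds)).integers(2**31))
            split = split_edges(net, f, seed=split_s)
            train = split.training_network
            for name, scorer, _ in resolved:
                table = scorer(train)
                res_auc = auc(
                    table, split, mode=auc_mode, n_samples=n_samples, seed=auc_s
                )
                res_prec = precision_at_L(table, split.probe)
                rows.append(
                    {
                        "network": network_name,
                        "method": name,
                        "f": f,
                        "run": run,
                        "auc": res_auc.auc,
                        "precision": res_prec.precision,
                    }
                )
    raw = pd.DataFrame(rows)
    summary = []
    for (name, f), group in raw.groupby(["method", "f"], sort=False):
        for metric in ("auc", "precision"):
            vals = group[metric].to_numpy()
            summary.append(
                {
                    "network": network_name,
                    "method": name,
                    "f": f,
                    "metric": metric,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=0)),
                    "runs": runs,
                }
            )
    config = {
        "methods": [
            {"name": name, "params": params} for name, _, params in resolved
        ],
        "fractions": list(fractions),
        "auc_mode": auc_mode,
        "n_samples": n_samples,
    }
    return BenchmarkReport(
        frame=pd.DataFrame(summary), raw=raw, runs=runs, seed=seed, config=config
    )


def format_mean_sd(mean: float, sd: float) -> str:
    """Render a benchmark cell as ``0.6994(162)``: four-decimal mean with the
    standard deviation in units of 1e-4 in brackets."""
    return f"{mean:.4f}({int(round(sd * 1e4))})"
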