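"""Train/probe splitting, AUC, precision and the benchmarking protocol."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nflink as nfl

import oracles


def iid_table(net, seed):
    """Uniform(0,1) scores on every non-observed pair."""
    pairs, _, _ = nfl.non_observed_pairs(net)
    rng = np.random.default_rng(seed)
    return nfl.ScoreTable(pairs=tuple(pairs), scores=rng.random(len(pairs)),
                          method="iid")


def constant_table(net, value=1.0):
    pairs, _, _ = nfl.non_observed_pairs(net)
    return nfl.ScoreTable(pairs=tuple(pairs),
                          scores=np.full(len(pairs), value), method="const")


class TestSplitEdges:
    def test_f_one_keeps_everything(self):
        net = nfl.erdos_renyi(20, 0.3, seed=1)
        split = nfl.split_edges(net, 1.0, seed=0)
        assert split.probe == frozenset()
        assert split.training == net.edges

    def test_cardinalities_disjoint_union(self):
        net = nfl.erdos_renyi(10, 0.25, seed=8)
        assert net.n_edges >= 10
        ten = nfl.Network.from_edges(net.edge_list()[:10], nodes=net.nodes)
        split = nfl.split_edges(ten, 0.9, seed=3)
        assert len(split.training) == 9 and len(split.probe) == 1
        assert split.training | split.probe == ten.edges
        assert not split.training & split.probe

    def test_determinism_and_seed_sensitivity(self):
        net = nfl.erdos_renyi(40, 0.15, seed=12)
        assert net.n_edges >= 100
        a = nfl.split_edges(net, 0.9, seed=5)
        b = nfl.split_edges(net, 0.9, seed=5)
        c = nfl.split_edges(net, 0.9, seed=6)
        assert a.training == b.training
        assert a.training != c.training

    def test_training_network_keeps_node_universe(self):
        net = nfl.erdos_renyi(20, 0.1, seed=2)
        split = nfl.split_edges(net, 0.5, seed=1)
        assert split.training_network.nodes == net.nodes

    def test_invalid_fraction_rejected(self):
        net = nfl.erdos_renyi(10, 0.3, seed=1)
        for bad in (0.0, -0.1, 1.2):
            with pytest.raises(ValueError, match="fraction"):
                nfl.split_edges(net, bad)


class TestAUC:
    def test_perfect_separation_scores_one(self):
        net = nfl.erdos_renyi(15, 0.3, seed=4)
        split = nfl.split_edges(net, 0.7, seed=4)
        pairs, _, _ = nfl.non_observed_pairs(split.training_network)
        probe = {frozenset(p) for p in split.probe}
        scores = np.array([1.0 if frozenset(p) in probe else 0.0
                           for p in pairs])
        table = nfl.ScoreTable(pairs=tuple(pairs), scores=scores, method="x")
        assert nfl.auc(table, split, mode="exact").auc == 1.0
        assert nfl.auc(table, split, mode="sampled", n_samples=2000,
                       seed=0).auc == 1.0

    def test_all_tied_scores_half(self):
        net = nfl.erdos_renyi(15, 0.3, seed=4)
        split = nfl.split_edges(net, 0.7, seed=4)
        table = constant_table(split.training_network)
        res = nfl.auc(table, split, mode="exact")
        assert res.auc == 0.5
        assert res.n_tied == res.n_comparisons

    def test_sampled_tracks_exact(self):
        """Monte-Carlo AUC within 3 standard errors of the exact value."""
        for seed in range(20):
            net = nfl.erdos_renyi(30, 0.15, seed=100 + seed)
            split = nfl.split_edges(net, 0.8, seed=seed)
            table = nfl.ra_scores(split.training_network)
            exact = nfl.auc(table, split, mode="exact").auc
            n_s = 20_000
            sampled = nfl.auc(table, split, mode="sampled", n_samples=n_s,
                              seed=seed).auc
            assert abs(sampled - exact) <= 3 * math.sqrt(0.25 / n_s)

    def test_exact_matches_pairwise_loop_oracle(self):
        net = nfl.erdos_renyi(12, 0.3, seed=6)
        split = nfl.split_edges(net, 0.7, seed=6)
        table = nfl.cn_scores(split.training_network)
        probe = {frozenset(p) for p in split.probe}
        pos = [s for p, s in zip(table.pairs, table.scores)
               if frozenset(p) in probe]
        neg = [s for p, s in zip(table.pairs, table.scores)
               if frozenset(p) not in probe]
        res = nfl.auc(table, split, mode="exact")
        assert math.isclose(res.auc, oracles.auc_pairwise(pos, neg),
                            abs_tol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 5000))
    def test_monotone_transform_invariance_and_negation(self, seed):
        net = nfl.erdos_renyi(15, 0.25, seed=seed % 97)
        if net.n_edges < 4:
            return
        split = nfl.split_edges(net, 0.75, seed=seed)
        if not split.probe:
            return
        table = iid_table(split.training_network, seed)
        base = nfl.auc(table, split, mode="exact").auc
        warped = nfl.ScoreTable(pairs=table.pairs,
                                scores=np.exp(3 * table.scores) - 1,
                                method="warp")
        negated = nfl.ScoreTable(pairs=table.pairs, scores=-table.scores,
                                 method="neg")
        assert math.isclose(nfl.auc(warped, split, mode="exact").auc, base,
                            abs_tol=1e-12)
        assert math.isclose(
            base + nfl.auc(negated, split, mode="exact").auc, 1.0,
            abs_tol=1e-12)

    def test_empty_probe_is_an_error(self):
        net = nfl.erdos_renyi(15, 0.3, seed=4)
        split = nfl.split_edges(net, 1.0, seed=4)
        table = iid_table(split.training_network, 0)
        with pytest.raises(ValueError, match="probe"):
            nfl.auc(table, split, mode="exact")


class TestPrecision:
    def test_perfect_ranking(self):
        net = nfl.erdos_renyi(15, 0.3, seed=4)
        split = nfl.split_edges(net, 0.7, seed=4)
        pairs, _, _ = nfl.non_observed_pairs(split.training_network)
        probe = {frozenset(p) for p in split.probe}
        scores = np.array([1.0 if frozenset(p) in probe else 0.0
                           for p in pairs])
        table = nfl.ScoreTable(pairs=tuple(pairs), scores=scores, method="x")
        res = nfl.precision_at_L(table, split.probe)
        assert res.precision == 1.0
        assert res.L == len(split.probe)

    def test_no_probe_in_top_L(self):
        net = nfl.erdos_renyi(15, 0.3, seed=4)
        split = nfl.split_edges(net, 0.7, seed=4)
        pairs, _, _ = nfl.non_observed_pairs(split.training_network)
        probe = {frozenset(p) for p in split.probe}
        rng = np.random.default_rng(0)
        jitter = rng.permutation(len(pairs)) / (10.0 * len(pairs))
        scores = np.array([0.0 if frozenset(p) in probe else 1.0
                           for p in pairs]) + jitter
        table = nfl.ScoreTable(pairs=tuple(pairs), scores=scores, method="x")
        assert nfl.precision_at_L(table, split.probe).precision == 0.0

    def test_fractional_tie_credit(self):
        """10 all-tied pairs, 4 of them probe links, L = 5 -> 0.4."""
        from nflink.metrics import precision_fraction
        pos = np.ones(4)
        neg = np.ones(6)
        precision, l_corr = precision_fraction(pos, neg, L=5)
        assert math.isclose(precision, 0.4)
        assert math.isclose(l_corr, 2.0)

    def test_fractional_credit_matches_enumeration(self):
        """Tie handling equals the exhaustive expectation over tie orders."""
        from nflink.metrics import precision_fraction
        rng = np.random.default_rng(7)
        for _ in range(25):
            n_pos = int(rng.integers(1, 5))
            n_neg = int(rng.integers(1, 6))
            levels = rng.integers(0, 3, size=n_pos + n_neg) / 2.0
            pos, neg = levels[:n_pos], levels[n_pos:]
            L = int(rng.integers(1, n_pos + n_neg + 1))
            ours, _ = precision_fraction(pos, neg, L)
            ref = oracles.precision_enumerated(list(pos), list(neg), L)
            assert math.isclose(ours, ref, abs_tol=1e-12)

    def test_demoting_a_hit_cannot_raise_precision(self):
        net = nfl.erdos_renyi(20, 0.2, seed=9)
        split = nfl.split_edges(net, 0.8, seed=9)
        table = nfl.ra_scores(split.training_network)
        before = nfl.precision_at_L(table, split.probe).precision
        probe_keys = {frozenset(p) for p in split.probe}
        scores = table.scores.copy()
        hit = next(i for i, p in enumerate(table.pairs)
                   if frozenset(p) in probe_keys)
        scores[hit] = -1e12
        demoted = nfl.ScoreTable(pairs=table.pairs, scores=scores, method="x")
        assert nfl.precision_at_L(demoted, split.probe).precision <= before

    def test_L_bounds_validated(self):
        net = nfl.erdos_renyi(10, 0.3, seed=4)
        split = nfl.split_edges(net, 0.7, seed=4)
        table = iid_table(split.training_network, 1)
        with pytest.raises(ValueError):
            nfl.precision_at_L(table, split.probe, L=len(table) + 1)
        with pytest.raises(ValueError):
            nfl.precision_at_L(table, split.probe, L=0)


class TestBenchmark:
    def test_single_run_has_zero_sd(self):
        net = nfl.erdos_renyi(25, 0.2, seed=3)
        rep = nfl.run_benchmark(net, ["CN"], fractions=[0.8], runs=1, seed=1)
        assert (rep.frame["sd"] == 0).all()

    def test_same_master_seed_reproduces_report(self):
        net = nfl.erdos_renyi(25, 0.2, seed=3)
        a = nfl.run_benchmark(net, ["CN", ("NF", {"t": 4})], fractions=[0.8],
                              runs=3, seed=11)
        b = nfl.run_benchmark(net, ["CN", ("NF", {"t": 4})], fractions=[0.8],
                              runs=3, seed=11)
        assert a.frame.equals(b.frame)

    def test_structured_graph_beats_chance(self):
        """On a planted partition, NF, CN and RA separate from AUC = 0.5 by
        more than three standard errors of the mean."""
        net = nfl.planted_partition(100, 4, 0.25, 0.01, seed=19)
        runs = 20
        rep = nfl.run_benchmark(
            net, [("NF", {"t": 5}), "CN", "RA"], fractions=[0.9], runs=runs,
            seed=23,
        )
        for method in ("NF", "CN", "RA"):
            mean, sd = rep.cell(method, 0.9, "auc")
            sem = sd / math.sqrt(runs)
            assert mean - 0.5 > 3 * sem, method

    def test_formatting_convention(self):
        assert nfl.format_mean_sd(0.6994, 0.0162) == "0.6994(162)"
        assert nfl.format_mean_sd(0.5, 0.0) == "0.5000(0)"
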