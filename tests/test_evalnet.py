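import numpy as np
import pytest

from spikete.evalnet import (
    degree_day_correlation,
    degrees,
    distance_edge_proportions,
    fisher_combine,
    precision_recall,
    roc_auc,
    roc_curve,
)
from spikete.events_io import ElectrodeLayout
from spikete.greedy import InferredNetwork
from spikete.lifsim import GroundTruthNetwork


def make_truth(n, edges, n_exc=None):
    A = np.zeros((n, n), dtype=np.int8)
    for s, t in edges:
        A[t, s] = 1
    is_exc = np.zeros(n, dtype=bool)
    is_exc[: (n_exc if n_exc is not None else n)] = True
    return GroundTruthNetwork(A=A, is_excitatory=is_exc,
                              strengths=np.where(is_exc, 1.0, -1.0))


def make_net(nodes, edges):
    return InferredNetwork(
        nodes=tuple(nodes),
        edges={e: {"n_intervals": 1, "p": 0.0, "te": 1.0} for e in edges},
    )


class TestPrecisionRecall:
    def test_basic_arithmetic(self):
        truth = make_truth(4, [(0, 1), (0, 2), (0, 3)])
        inferred = make_net("0123", [("0", "1"), ("0", "2"), ("0", "3"), ("1", "2")])
        m = precision_recall(inferred, truth, node_order=list("0123"))
        assert m.precision["pooled"] == 0.75
        assert m.recall["pooled"] == 1.0

    def test_perfect_inference(self):
        edges = [(0, 1), (2, 3), (3, 0)]
        truth = make_truth(4, edges)
        inferred = make_net("0123", [(str(s), str(t)) for s, t in edges])
        m = precision_recall(inferred, truth, node_order=list("0123"))
        assert m.precision["pooled"] == m.recall["pooled"] == 1.0

    def test_weighted_average_uses_true_edge_counts(self):
        # 3 excitatory-source + 2 inhibitory-source true edges; perfect
        # excitatory recall, zero inhibitory recall -> weighted 0.6
        truth = make_truth(6, [(0, 3), (1, 3), (2, 3), (4, 3), (5, 3)], n_exc=3)
        inferred = make_net(
            [str(i) for i in range(6)], [("0", "3"), ("1", "3"), ("2", "3")]
        )
        m = precision_recall(inferred, truth, node_order=[str(i) for i in range(6)])
        assert m.recall["exc"] == 1.0 and m.recall["inh"] == 0.0
        assert m.recall["overall"] == pytest.approx(0.6)

    def test_no_predictions_gives_nan_precision(self):
        truth = make_truth(3, [(0, 1)])
        m = precision_recall(make_net("012", []), truth, node_order=list("012"))
        assert np.isnan(m.precision["pooled"])
        assert m.recall["pooled"] == 0.0

    def test_metrics_within_unit_interval_and_between_classes(self):
        rng = np.random.default_rng(0)
        n = 8
        all_pairs = [(s, t) for s in range(n) for t in range(n) if s != t]
        truth_edges = [all_pairs[i] for i in rng.choice(len(all_pairs), 20, False)]
        truth = make_truth(n, truth_edges, n_exc=5)
        guess = [all_pairs[i] for i in rng.choice(len(all_pairs), 15, False)]
        m = precision_recall(
            make_net([str(i) for i in range(n)],
                     [(str(s), str(t)) for s, t in guess]),
            truth, node_order=[str(i) for i in range(n)],
        )
        vals = [v for v in m.precision.values() if not np.isnan(v)]
        assert all(0 <= v <= 1 for v in vals)
        lo, hi = sorted([m.recall["exc"], m.recall["inh"]])
        assert lo - 1e-12 <= m.recall["overall"] <= hi + 1e-12


class TestROC:
    def test_endpoints(self):
        truth = make_truth(3, [(0, 1), (1, 2)])
        order = list("012")
        p = {}
        rng = np.random.default_rng(1)
        for s in order:
            for t in order:
                if s != t:
                    p[(s, t)] = rng.uniform(0.01, 0.99)
        curve = roc_curve(p, truth, alpha_grid=[0.0, 0.5, 1.0], node_order=order)
        assert curve.tpr[-1] == 1.0 and curve.fpr[-1] == 1.0
        assert np.all(np.diff(curve.tpr) >= 0) and np.all(np.diff(curve.fpr) >= 0)

    def test_alpha_zero_keeps_only_p_zero_edges(self):
        truth = make_truth(3, [(0, 1)])
        p = {("0", "1"): 0.0, ("1", "0"): 0.2, ("0", "2"): 0.5,
             ("2", "0"): 0.5, ("1", "2"): 0.5, ("2", "1"): 0.5}
        curve = roc_curve(p, truth, [0.0], node_order=list("012"))
        assert curve.tpr[0] == 1.0 and curve.fpr[0] == 0.0

    def test_auc_orders_good_vs_random(self):
        truth = make_truth(4, [(0, 1), (1, 2), (2, 3)])
        order = list("0123")
        good, bad = {}, {}
        rng = np.random.default_rng(2)
        for s in order:
            for t in order:
                if s == t:
                    continue
                is_true = (int(s), int(t)) in {(0, 1), (1, 2), (2, 3)}
                good[(s, t)] = 0.01 if is_true else rng.uniform(0.3, 1)
                bad[(s, t)] = rng.uniform(0, 1)
        grid = np.linspace(0, 1, 21)
        auc_good = roc_auc(roc_curve(good, truth, grid, node_order=order))
        auc_bad = roc_auc(roc_curve(bad, truth, grid, node_order=order))
        assert auc_good > auc_bad


class TestDegrees:
    def test_degree_counts(self):
        net = make_net("abc", [("a", "b"), ("a", "c"), ("b", "c")])
        indeg, outdeg = degrees(net)
        assert indeg == {"a": 0, "b": 1, "c": 2}
        assert outdeg == {"a": 2, "b": 1, "c": 0}
        assert sum(indeg.values()) == len(net.edges)

    def test_empty_network(self):
        indeg, outdeg = degrees(make_net("ab", []))
        assert set(indeg.values()) == {0} and set(outdeg.values()) == {0}


class TestDegreeCorrelation:
    def test_identical_and_reversed(self):
        d1 = {str(i): i for i in range(6)}
        d2 = {str(i): 5 - i for i in range(6)}
        assert degree_day_correlation(d1, d1).rho == 1.0
        assert degree_day_correlation(d1, d2).rho == -1.0

    def test_rank_formula_value(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d = (-1, 1, -1, 1, 0)
        d1 = {str(i): v for i, v in enumerate([1, 2, 3, 4, 5])}
        d2 = {str(i): v for i, v in enumerate([2, 1, 4, 3, 5])}
        assert degree_day_correlation(d1, d2).rho == pytest.approx(0.8)

    def test_jitter_only_affects_plot_coordinates(self):
        d1 = {str(i): i % 3 for i in range(9)}
        d2 = {str(i): (i + 1) % 3 for i in range(9)}
        a = degree_day_correlation(d1, d2, rng=np.random.default_rng(0))
        b = degree_day_correlation(d1, d2, rng=np.random.default_rng(99))
        assert a.rho == b.rho and a.p_one_sided == b.p_one_sided
        assert not np.allclose(a.jittered[0], b.jittered[0])

    def test_too_few_nodes(self):
        with pytest.raises(ValueError):
            degree_day_correlation({"a": 1, "b": 2}, {"a": 2, "b": 1})


class TestFisher:
    def test_values(self):
        assert fisher_combine([1.0, 1.0]) == pytest.approx(1.0)
        assert fisher_combine([0.3]) == pytest.approx(0.3)
        # -2*(ln .05 + ln .05) ~ 11.98 on chi2(4)
        assert fisher_combine([0.05, 0.05]) == pytest.approx(0.0174, abs=5e-4)

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])


class TestDistanceProportions:
    def layout22(self):
        return ElectrodeLayout(
            {"a": (0, 0), "b": (0, 1), "c": (1, 0), "d": (1, 1)}
        )

    def test_full_network_has_unit_proportions(self):
        nodes = list("abcd")
        edges = [(s, t) for s in nodes for t in nodes if s != t]
        props = distance_edge_proportions(make_net(nodes, edges), self.layout22())
        assert props == {1: 1.0, 2: 1.0}

    def test_empty_network(self):
        props = distance_edge_proportions(make_net("abcd", []), self.layout22())
        assert set(props.values()) == {0.0}

    def test_pair_counts_match_enumeration(self):
        # 2x2 grid: 8 ordered pairs at Manhattan distance 1, 4 at distance 2
        nodes = list("abcd")
        edges = [("a", "b")]  # distance 1
        props = distance_edge_proportions(make_net(nodes, edges), self.layout22())
        assert props[1] == pytest.approx(1 / 8)
        assert props[2] == 0.0
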