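"""Scoring of inferred networks against ground truth, and network summaries.

Precision = TP/(TP+FP) and recall = TP/(TP+FN) over directed edges, computed
per true-source class (excitatory / inhibitory afferents) and pooled; the
overall figure is the class metrics weighted by the true-edge counts of each
class.  ROC curves sweep the significance cutoff alpha; degree summaries,
between-day degree correlations (Spearman, with Fisher combination across
cultures) and distance-resolved edge proportions support developmental
analyses of recorded cultures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifiedMetrics",
    "ROCCurve",
    "precision_recall",
    "roc_curve",
    "roc_curve_from_networks",
    "roc_auc",
    "partial_roc_auc",
    "degrees",
    "degree_day_correlation",
    "fisher_combine",
    "distance_edge_proportions",
]


def _edge_set(network_or_edges):
    if hasattr(network_or_edges, "edge_set"):
        return set(network_or_edges.edge_set())
    if hasattr(network_or_edges, "edges") and not isinstance(
        network_or_edges.edges, dict
    ):
        return set(network_or_edges.edges())
    if hasattr(network_or_edges, "edges"):
        return set(network_or_edges.edges)
    return set(network_or_edges)


@dataclass(frozen=True)
class ClassifiedMetrics:
    """Confusion counts and precision/recall per source class and pooled."""

    counts: dict  # class -> dict(tp, fp, fn, tn)
    precision: dict  # class -> float or nan; includes "overall"
    recall: dict
    n_nodes: int

    def __getitem__(self, key):
        return {"precision": self.precision[key], "recall": self.recall[key]}


def _prf(tp, fp, fn):
    prec = tp / (tp + fp) if (tp + fp) else float("nan")
    rec = tp / (tp + fn) if (tp + fn) else float("nan")
    return prec, rec


def precision_recall(inferred, truth, node_order=None) -> ClassifiedMetrics:
    """Score ``inferred`` against a ground-truth network.

    ``truth`` is a ground-truth network object with ``edges()`` returning
    ordered (source, target) pairs and ``is_excitatory`` per node; edges are
    classified by the class of their true source.  With zero predicted edges
    the precision is undefined and reported as NaN (not zero).  The overall
    precision/recall weight the class values by true-edge counts.
    """
    pred = _edge_set(inferred)
    true_edges = set(truth.edges())
    n = truth.n
    if node_order is None:
        node_order = [str(i) for i in range(n)]
    to_idx = {u: i for i, u in enumerate(node_order)}
    pred_idx = {(to_idx[s], to_idx[t]) for s, t in pred}

    classes = {"exc": None, "inh": None}
    counts, precision, recall = {}, {}, {}
    w_tp = w_fp = w_fn = 0
    class_weights, class_prec, class_rec = [], [], []
    for cname in classes:
        exc = cname == "exc"
        t_edges = {e for e in true_edges if truth.is_excitatory[e[0]] == exc}
        p_edges = {e for e in pred_idx if truth.is_excitatory[e[0]] == exc}
        tp = len(t_edges & p_edges)
        fp = len(p_edges - t_edges)
        fn = len(t_edges - p_edges)
        possible = sum(
            1
            for s in range(n)
            for t in range(n)
            if s != t and truth.is_excitatory[s] == exc
        )
        tn = possible - tp - fp - fn
        counts[cname] = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
        p, r = _prf(tp, fp, fn)
        precision[cname], recall[cname] = p, r
        w_tp += tp
        w_fp += fp
        w_fn += fn
        class_weights.append(len(t_edges))
        class_prec.append(p)
        class_rec.append(r)
        if tp + fp == 0:
            logger.info("no predicted %s-source edges; precision undefined", cname)

    counts["pooled"] = {"tp": w_tp, "fp": w_fp, "fn": w_fn,
                        "tn": n * (n - 1) - w_tp - w_fp - w_fn}
    precision["pooled"], recall["pooled"] = _prf(w_tp, w_fp, w_fn)

    w = np.array(class_weights, dtype=float)
    if w.sum() > 0:
        pr = np.array(class_prec)
        rc = np.array(class_rec)
        ok_p = ~np.isnan(pr)
        ok_r = ~np.isnan(rc)
        precision["overall"] = (
            float(np.sum(w[ok_p] * pr[ok_p]) / np.sum(w[ok_p]))
            if ok_p.any()
            else float("nan")
        )
        recall["overall"] = (
            float(np.sum(w[ok_r] * rc[ok_r]) / np.sum(w[ok_r]))
            if ok_r.any()
            else float("nan")
        )
    else:
        precision["overall"] = recall["overall"] = float("nan")
    return ClassifiedMetrics(counts, precision, recall, n)


@dataclass(frozen=True)
class ROCCurve:
    """(FPR, TPR) per alpha cutoff; non-decreasing in alpha by construction."""

    alphas: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    mode: str = "pairwise"
    p_method: str = "empirical"


def roc_curve(
    p_values: dict,
    truth,
    alpha_grid,
    node_order=None,
    mode: str = "pairwise",
    p_method: str = "empirical",
) -> ROCCurve:
    """ROC from a p-value matrix: an edge is inferred when p <= alpha.

    ``p_values`` maps ordered (source, target) unit-id pairs to p-values.
    """
    n = truth.n
    if node_order is None:
        node_order = [str(i) for i in range(n)]
    to_idx = {u: i for i, u in enumerate(node_order)}
    true_edges = set(truth.edges())
    n_pos = len(true_edges)
    n_neg = n * (n - 1) - n_pos
    alphas = np.sort(np.asarray(alpha_grid, dtype=float))
    fpr = np.empty(alphas.size)
    tpr = np.empty(alphas.size)
    items = [((to_idx[s], to_idx[t]), p) for (s, t), p in p_values.items()]
    for i, a in enumerate(alphas):
        pred = {e for e, p in items if p <= a}
        tp = len(pred & true_edges)
        fp = len(pred - true_edges)
        tpr[i] = tp / n_pos if n_pos else float("nan")
        fpr[i] = fp / n_neg if n_neg else float("nan")
    return ROCCurve(alphas, fpr, tpr, mode=mode, p_method=p_method)


def roc_curve_from_networks(networks_per_alpha, truth, node_order=None) -> ROCCurve:
    """ROC points from greedy runs at each alpha (pruning excluded upstream)."""
    alphas = np.array(sorted(networks_per_alpha), dtype=float)
    n = truth.n
    if node_order is None:
        node_order = [str(i) for i in range(n)]
    to_idx = {u: i for i, u in enumerate(node_order)}
    true_edges = set(truth.edges())
    n_pos = len(true_edges)
    n_neg = n * (n - 1) - n_pos
    fpr, tpr = [], []
    for a in alphas:
        pred = {(to_idx[s], to_idx[t]) for s, t in _edge_set(networks_per_alpha[a])}
        tp = len(pred & true_edges)
        fp = len(pred - true_edges)
        tpr.append(tp / n_pos if n_pos else float("nan"))
        fpr.append(fp / n_neg if n_neg else float("nan"))
    # enforce monotone attainability (greedy stopping is stochastic in alpha)
    tpr = np.maximum.accumulate(tpr)
    fpr = np.array(fpr)
    return ROCCurve(alphas, fpr, np.asarray(tpr), mode="greedy-no-prune")


def roc_auc(curve: ROCCurve) -> float:
    """Trapezoidal AUC with (0,0) and (1,1) anchors."""
    f = np.concatenate([[0.0], curve.fpr, [1.0]])
    t = np.concatenate([[0.0], curve.tpr, [1.0]])
    order = np.argsort(f, kind="stable")
    return float(np.trapezoid(t[order], f[order]))


def partial_roc_auc(curve: ROCCurve, fpr_max: float) -> float:
    """Trapezoidal AUC over [0, fpr_max] with a (0,0) anchor only.

    Curves whose significance cutoff is bounded (the greedy sweep stops at
    alpha = 0.75) never reach (1,1); comparing areas over the commonly
    attained false-positive range avoids crediting either curve for
    extrapolated segments.
    """
    f = np.concatenate([[0.0], curve.fpr])
    t = np.concatenate([[0.0], curve.tpr])
    order = np.argsort(f, kind="stable")
    f, t = f[order], t[order]
    if fpr_max > f[-1]:
        f = np.append(f, fpr_max)
        t = np.append(t, t[-1])
    t_end = float(np.interp(fpr_max, f, t))
    keep = f <= fpr_max
    fs = np.append(f[keep], fpr_max)
    ts = np.append(t[keep], t_end)
    return float(np.trapezoid(ts, fs))


def degrees(network):
    """(in_degree, out_degree) dicts of a directed network."""
    g = network.to_networkx() if hasattr(network, "to_networkx") else network
    return dict(g.in_degree()), dict(g.out_degree())


@dataclass(frozen=True)
class DegreeCorrelation:
    rho: float
    p_one_sided: float
    slope: float
    intercept: float
    jittered: tuple = field(repr=False, default=())


def degree_day_correlation(deg_early, deg_late, jitter_sd: float = 0.1, rng=None):
    """Spearman correlation between matched node degrees on two days.

    The correlation and its one-sided p (positive association) are computed
    on the raw values; Gaussian jitter is applied only to the returned
    plotting coordinates, to separate repeated values.  An ordinary
    least-squares line is returned for display.
    """
    keys = sorted(set(deg_early) & set(deg_late), key=str)
    if len(keys) < 3:
        raise ValueError("need at least 3 matched nodes")
    x = np.array([deg_early[k] for k in keys], dtype=float)
    y = np.array([deg_late[k] for k in keys], dtype=float)
    rho, p_two = stats.spearmanr(x, y)
    if np.isnan(rho):
        raise ValueError("degenerate degree vectors (zero variance)")
    p_one = p_two / 2 if rho > 0 else 1 - p_two / 2
    slope, intercept = np.polyfit(x, y, 1)
    if rng is not None and jitter_sd > 0:
        xj = x + rng.normal(0, jitter_sd, x.size)
        yj = y + rng.normal(0, jitter_sd, y.size)
    else:
        xj, yj = x, y
    return DegreeCorrelation(
        float(rho), float(p_one), float(slope), float(intercept), (xj, yj)
    )


def fisher_combine(p_values) -> float:
    """Fisher's combination of independent p-values (chi-square, 2k df)."""
    p = np.asarray(p_values, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError(
            "p-values must lie in (0, 1]; substitute the machine minimum "
            "upstream for exact zeros"
        )
    stat, combined = stats.combine_pvalues(p, method="fisher")
    return float(combined)


def distance_edge_proportions(network, layout, node_order=None):
    """Proportion of possible ordered pairs inferred, per Manhattan distance.

    Pairs are binned by the cityblock distance between their electrodes'
    integer grid coordinates; nodes without coordinates are excluded (and
    logged).  Returns ``{distance: proportion}``.
    """
    edges = _edge_set(network)
    nodes = list(network.nodes) if hasattr(network, "nodes") else sorted(
        {u for e in edges for u in e}, key=str
    )
    missing = [u for u in nodes if u not in layout.positions]
    if missing:
        logger.info("nodes without coordinates excluded: %s", missing)
    nodes = [u for u in nodes if u in layout.positions]
    possible, inferred = {}, {}
    for s in nodes:
        rs, cs = layout.positions[s]
        for t in nodes:
            if s == t:
                continue
            rt, ct = layout.positions[t]
            d = abs(rs - rt) + abs(cs - ct)
            possible[d] = possible.get(d, 0) + 1
            if (s, t) in edges:
                inferred[d] = inferred.get(d, 0) + 1
    return {d: inferred.get(d, 0) / possible[d] for d in sorted(possible)}
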