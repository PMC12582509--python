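"""Greedy multivariate effective-network inference, plus a pairwise baseline.

Per target, the algorithm (i) chooses the number of target history intervals
to condition on via conditional active-information-storage increments,
(ii) greedily adds candidate source intervals — one interval per source per
round, sequentially from the most recent — keeping the candidate with the
highest bias-corrected conditional TE whenever it passes the familywise
maximum-statistic test, and (iii) prunes: repeatedly re-tests each source's
last added interval given everything else retained (plain empirical test)
and removes the weakest while it is non-significant.  Targets are
independent, so the whole procedure parallelises trivially across them.

The pairwise baseline simply tests each ordered pair for non-zero TE with a
single source interval and no conditioning; it retains the full p-value
matrix for ROC sweeps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator

from .ctte import EstimatorParams, estimate_with_surrogates
from .embedding import EmbeddingSpec
from .events_io import Recording
from .surrogate import max_statistic_p

logger = logging.getLogger(__name__)

__all__ = [
    "ParentSet",
    "InferredNetwork",
    "select_target_depth",
    "greedy_select",
    "prune",
    "infer_network",
    "pairwise_infer",
    "GreedyNetworkInference",
    "PairwiseNetworkInference",
]


@dataclass
class ParentSet:
    """Selected source intervals for one target, with per-step records."""

    target_id: object
    target_depth: int
    source_intervals: dict = field(default_factory=dict)
    addition_order: list = field(default_factory=list)
    records: list = field(default_factory=list)
    final_stats: dict = field(default_factory=dict)

    def _check(self):
        counts = {}
        for sid, j in self.addition_order:
            counts[sid] = counts.get(sid, 0) + 1
            if j != counts[sid]:
                raise ValueError("interval added out of sequence")

    @property
    def sources(self):
        return sorted(self.source_intervals, key=str)

    def depth_maps(self):
        """(source_depths, cond-style dict) of everything retained."""
        return dict(self.source_intervals)


@dataclass(frozen=True)
class InferredNetwork:
    """Directed effective network: edge (s -> t) iff s parents t."""

    nodes: tuple
    edges: dict  # (source, target) -> dict(n_intervals, p, te)
    parent_sets: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (s, t), attrs in self.edges.items():
            g.add_edge(s, t, **attrs)
        return g

    def edge_set(self):
        return set(self.edges)


def _candidate_estimate(recording, target_id, k, parents, cand_id, params, rng):
    """Conditional TE of ``cand_id``'s next unadded interval given the set."""
    depths = dict(parents.source_intervals)
    cand_lag = depths.get(cand_id, 0) + 1
    depths[cand_id] = cand_lag
    spec = EmbeddingSpec(target_depth=k, source_depths=depths)
    return estimate_with_surrogates(
        recording,
        target_id,
        spec,
        params,
        rng,
        source_cols=[(cand_id, cand_lag)],
    )


def select_target_depth(
    recording: Recording,
    target_id,
    params: EstimatorParams = None,
    alpha: float = 0.05,
    rng=None,
    max_target_depth: int = 5,
    counter=None,
) -> int:
    """Number of target history intervals to condition on.

    The most recent interval is always included; the depth is then grown
    while the storage increment of the next (oldest considered) interval is
    significant at ``alpha`` (plain empirical test), capped at
    ``max_target_depth``.
    """
    from .ctte import conditional_ais_increment

    params = params or EstimatorParams()
    rng = params.rng(rng)
    depth = 1
    while depth < max_target_depth:
        est = conditional_ais_increment(
            recording, target_id, depth + 1, params=params, rng=rng
        )
        if counter is not None:
            counter["n_te_calls"] += 1 + params.n_surrogates
        if est.p_empirical >= alpha:
            return depth
        depth += 1
    logger.info("target %s: max_target_depth=%d reached", target_id, max_target_depth)
    return depth


def greedy_select(
    recording: Recording,
    target_id,
    k: int,
    params: EstimatorParams = None,
    alpha: float = 0.05,
    rng=None,
    max_source_intervals: int = 3,
    counter=None,
) -> ParentSet:
    """Greedy addition of source intervals under the maximum-statistic test."""
    params = params or EstimatorParams()
    rng = params.rng(rng)
    parents = ParentSet(target_id=target_id, target_depth=k)
    others = [u for u in recording.unit_ids if u != target_id]
    while True:
        cands, estimates = [], []
        for cid in others:
            if parents.source_intervals.get(cid, 0) >= max_source_intervals:
                continue
            try:
                est = _candidate_estimate(
                    recording, target_id, k, parents, cid, params, rng
                )
            except ValueError as e:
                logger.debug("candidate %s skipped: %s", cid, e)
                continue
            if counter is not None:
                counter["n_te_calls"] += 1 + params.n_surrogates
            cands.append(cid)
            estimates.append(est)
        if not cands:
            break
        originals = np.array([e.bias_corrected_rate for e in estimates])
        surr = np.vstack([e.bias_corrected_surrogates for e in estimates])
        winner, p = max_statistic_p(originals, surr)
        cid = cands[winner]
        if p >= alpha:
            parents.records.append(
                {"step": "stop", "candidate": cid, "p": p,
                 "te": float(originals[winner])}
            )
            break
        lag = parents.source_intervals.get(cid, 0) + 1
        parents.source_intervals[cid] = lag
        parents.addition_order.append((cid, lag))
        parents.records.append(
            {
                "step": "add",
                "source": cid,
                "interval": lag,
                "te": float(estimates[winner].rate),
                "te_corrected": float(originals[winner]),
                "p": p,
            }
        )
    parents._check()
    return parents


def prune(
    recording: Recording,
    target_id,
    parents: ParentSet,
    params: EstimatorParams = None,
    alpha: float = 0.05,
    rng=None,
    counter=None,
) -> ParentSet:
    """Remove redundant intervals, last-added-first per source.

    Each round re-estimates, for every retained source, the conditional TE of
    its *last* remaining interval given all other retained intervals, with a
    plain empirical test (explicitly not the maximum-statistic test, since no
    selection is made here); the interval with the largest p is removed if
    p > alpha, and fresh surrogates are generated every round.
    """
    params = params or EstimatorParams()
    rng = params.rng(rng)
    pruned = ParentSet(
        target_id=parents.target_id,
        target_depth=parents.target_depth,
        source_intervals=dict(parents.source_intervals),
        addition_order=list(parents.addition_order),
        records=list(parents.records),
    )
    while pruned.source_intervals:
        worst_p, worst_sid = -1.0, None
        round_stats = {}
        for sid in pruned.sources:
            lag = pruned.source_intervals[sid]
            spec = EmbeddingSpec(
                target_depth=pruned.target_depth,
                source_depths=dict(pruned.source_intervals),
            )
            est = estimate_with_surrogates(
                recording,
                target_id,
                spec,
                params,
                rng,
                source_cols=[(sid, lag)],
            )
            if counter is not None:
                counter["n_te_calls"] += 1 + params.n_surrogates
            round_stats[sid] = {
                "n_intervals": lag,
                "te": est.bias_corrected_rate,
                "p": est.p_empirical,
            }
            if est.p_empirical > worst_p:
                worst_p, worst_sid = est.p_empirical, sid
        if worst_sid is None or worst_p <= alpha:
            pruned.final_stats = round_stats
            break
        lag = pruned.source_intervals[worst_sid]
        pruned.records.append(
            {"step": "prune", "source": worst_sid, "interval": lag, "p": worst_p}
        )
        if lag == 1:
            del pruned.source_intervals[worst_sid]
        else:
            pruned.source_intervals[worst_sid] = lag - 1
    return pruned


def infer_network(
    recording: Recording,
    params: EstimatorParams = None,
    alpha: float = 0.05,
    prune_flag: bool = True,
    rng=None,
    max_target_depth: int = 5,
    max_source_intervals: int = 3,
) -> InferredNetwork:
    """Run depth selection, greedy selection and optional pruning per target."""
    params = params or EstimatorParams()
    rng = params.rng(rng)
    edges, parent_sets = {}, {}
    counter = {"n_te_calls": 0}
    for target_id in recording.unit_ids:
        try:
            k = select_target_depth(
                recording, target_id, params, alpha, rng, max_target_depth, counter
            )
            parents = greedy_select(
                recording, target_id, k, params, alpha, rng,
                max_source_intervals, counter,
            )
            if prune_flag and parents.source_intervals:
                parents = prune(
                    recording, target_id, parents, params, alpha, rng, counter
                )
            if parents.final_stats:
                stats = parents.final_stats
            else:
                stats = {
                    sid: {
                        "n_intervals": parents.source_intervals[sid],
                        "te": next(
                            (r.get("te_corrected") for r in reversed(parents.records)
                             if r.get("step") == "add" and r.get("source") == sid),
                            float("nan"),
                        ),
                        "p": next(
                            (r.get("p") for r in reversed(parents.records)
                             if r.get("step") == "add" and r.get("source") == sid),
                            float("nan"),
                        ),
                    }
                    for sid in parents.sources
                }
        except ValueError as e:
            logger.warning("target %s skipped: %s", target_id, e)
            continue
        parent_sets[target_id] = parents
        for sid, st in stats.items():
            edges[(sid, target_id)] = st
    return InferredNetwork(
        nodes=tuple(recording.unit_ids),
        edges=edges,
        parent_sets=parent_sets,
        metadata={
            "alpha": alpha,
            "pruned": prune_flag,
            "params": params,
            "n_te_calls": counter["n_te_calls"],
        },
    )


def pairwise_infer(
    recording: Recording,
    params: EstimatorParams = None,
    alpha: float = 0.05,
    rng=None,
    max_target_depth: int = 5,
):
    """Pairwise (functional-network) baseline: test every ordered pair.

    Returns the inferred network and the full empirical / normal p-value
    matrices (dicts keyed by (source, target)) for ROC sweeps.
    """
    from .ctte import conditional_te_rate

    params = params or EstimatorParams()
    rng = params.rng(rng)
    p_emp, p_norm, te = {}, {}, {}
    edges = {}
    for target_id in recording.unit_ids:
        try:
            k = select_target_depth(
                recording, target_id, params, alpha, rng, max_target_depth
            )
        except ValueError as e:
            logger.warning("target %s skipped: %s", target_id, e)
            continue
        for source_id in recording.unit_ids:
            if source_id == target_id:
                continue
            try:
                est = conditional_te_rate(
                    recording, target_id, source_id,
                    target_depth=k, source_depth=1, params=params, rng=rng,
                )
            except ValueError as e:
                logger.warning("pair %s->%s skipped: %s", source_id, target_id, e)
                continue
            p_emp[(source_id, target_id)] = est.p_empirical
            p_norm[(source_id, target_id)] = est.p_normal
            te[(source_id, target_id)] = est.bias_corrected_rate
            if est.p_empirical < alpha:
                edges[(source_id, target_id)] = {
                    "n_intervals": 1,
                    "te": est.bias_corrected_rate,
                    "p": est.p_empirical,
                }
    net = InferredNetwork(
        nodes=tuple(recording.unit_ids),
        edges=edges,
        metadata={"alpha": alpha, "mode": "pairwise", "params": params},
    )
    return net, {"empirical": p_emp, "normal": p_norm, "te": te}


class GreedyNetworkInference(BaseEstimator):
    """Effective-network inference estimator (scikit-learn conventions).

    Parameters mirror :class:`~spikete.ctte.EstimatorParams` plus the
    algorithm's cutoff and caps.  ``fit`` takes a :class:`Recording` and sets
    ``network_``, ``parent_sets_`` and ``n_te_calls_``.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        k_global: int = 4,
        k_perm: int = 20,
        nu_multiplier: float = 20.0,
        nu_surrogate_multiplier: float = 20.0,
        n_surrogates: int = 100,
        norm: str = "chebyshev",
        tie_noise: float = 1e-10,
        sampling: str = "uniform",
        max_target_depth: int = 5,
        max_source_intervals: int = 3,
        prune: bool = True,
        random_state: int | None = None,
    ):
        self.alpha = alpha
        self.k_global = k_global
        self.k_perm = k_perm
        self.nu_multiplier = nu_multiplier
        self.nu_surrogate_multiplier = nu_surrogate_multiplier
        self.n_surrogates = n_surrogates
        self.norm = norm
        self.tie_noise = tie_noise
        self.sampling = sampling
        self.max_target_depth = max_target_depth
        self.max_source_intervals = max_source_intervals
        self.prune = prune
        self.random_state = random_state

    def _params(self) -> EstimatorParams:
        return EstimatorParams(
            k_global=self.k_global,
            k_perm=self.k_perm,
            nu_multiplier=self.nu_multiplier,
            nu_surrogate_multiplier=self.nu_surrogate_multiplier,
            n_surrogates=self.n_surrogates,
            norm=self.norm,
            tie_noise=self.tie_noise,
            sampling=self.sampling,
            seed=self.random_state,
        )

    def fit(self, recording: Recording, y=None):
        if recording.n_units < 2:
            raise ValueError("need at least two spike trains")
        net = infer_network(
            recording,
            params=self._params(),
            alpha=self.alpha,
            prune_flag=self.prune,
            max_target_depth=self.max_target_depth,
            max_source_intervals=self.max_source_intervals,
        )
        self.network_ = net
        self.parent_sets_ = net.parent_sets
        self.n_te_calls_ = net.metadata["n_te_calls"]
        return self

    def predict(self, recording: Recording = None):
        """Adjacency matrix over the fitted node order (a[i, j]: j -> i)."""
        if not hasattr(self, "network_"):
            raise AttributeError("estimator is not fitted")
        nodes = list(self.network_.nodes)
        a = np.zeros((len(nodes), len(nodes)), dtype=np.int8)
        for s, t in self.network_.edges:
            a[nodes.index(t), nodes.index(s)] = 1
        return a


class PairwiseNetworkInference(BaseEstimator):
    """Pairwise TE baseline with the same parameter surface.

    ``fit`` sets ``network_`` and ``p_matrix_`` (empirical and normal
    p-values per ordered pair).
    """

    def __init__(
        self,
        alpha: float = 0.05,
        k_global: int = 4,
        k_perm: int = 20,
        nu_multiplier: float = 20.0,
        nu_surrogate_multiplier: float = 20.0,
        n_surrogates: int = 100,
        norm: str = "chebyshev",
        tie_noise: float = 1e-10,
        sampling: str = "uniform",
        max_target_depth: int = 5,
        random_state: int | None = None,
    ):
        self.alpha = alpha
        self.k_global = k_global
        self.k_perm = k_perm
        self.nu_multiplier = nu_multiplier
        self.nu_surrogate_multiplier = nu_surrogate_multiplier
        self.n_surrogates = n_surrogates
        self.norm = norm
        self.tie_noise = tie_noise
        self.sampling = sampling
        self.max_target_depth = max_target_depth
        self.random_state = random_state

    def fit(self, recording: Recording, y=None):
        if recording.n_units < 2:
            raise ValueError("need at least two spike trains")
        params = EstimatorParams(
            k_global=self.k_global,
            k_perm=self.k_perm,
            nu_multiplier=self.nu_multiplier,
            nu_surrogate_multiplier=self.nu_surrogate_multiplier,
            n_surrogates=self.n_surrogates,
            norm=self.norm,
            tie_noise=self.tie_noise,
            sampling=self.sampling,
            seed=self.random_state,
        )
        net, pmat = pairwise_infer(
            recording, params=params, alpha=self.alpha,
            max_target_depth=self.max_target_depth,
        )
        self.network_ = net
        self.p_matrix_ = pmat
        return self
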