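"""Inter-spike-interval history embeddings and estimator sample sets.

A history embedding of a process at time ``t`` is the vector
``[t - t_last, ISI_1, ..., ISI_(depth-1)]`` — the time since the most recent
spike strictly before ``t``, followed by the preceding inter-spike intervals,
most recent first.  Representing history this way keeps the state space
low-dimensional while preserving full timing precision, which is what makes
nearest-neighbour estimation of history-conditional firing rates feasible.

A :class:`SampleSet` holds joint embeddings evaluated at the target's spike
times (``X``) and at random sample times (``U``).  The two matrices share a
column layout; a designated *source block* of columns can be dropped to
obtain the marginal-space sample set, or permuted to generate surrogates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .events_io import Recording, SpikeTrain

__all__ = [
    "EmbeddingSpec",
    "SampleSet",
    "history_embedding",
    "embed_at_times",
    "uniform_sample_times",
    "spike_anchored_sample_times",
    "assemble_sample_set",
]


@dataclass(frozen=True)
class EmbeddingSpec:
    """Depths of the history embeddings entering one estimate.

    ``target_depth`` counts target history intervals (at least one when the
    spec backs a TE or storage estimate); ``source_depths`` and
    ``cond_depths`` map process ids to interval counts.
    """

    target_depth: int
    source_depths: dict = field(default_factory=dict)
    cond_depths: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.target_depth < 1:
            raise ValueError("target_depth must be >= 1")
        for d in list(self.source_depths.values()) + list(self.cond_depths.values()):
            if d < 0:
                raise ValueError("embedding depths must be >= 0")

    def depth_map(self, target_id) -> dict:
        """Total per-process depths, target first, overlaps summed is an error."""
        depths = {target_id: self.target_depth}
        for m in (self.cond_depths, self.source_depths):
            for pid, d in m.items():
                if d == 0:
                    continue
                if pid in depths:
                    raise ValueError(f"process {pid!r} appears twice in the spec")
                depths[pid] = d
        return depths


@dataclass(frozen=True)
class SampleSet:
    """Joint history embeddings at target spikes (X) and sample times (U).

    ``columns`` records ``(process_id, lag)`` per column, lag 1 being the
    most recent interval.  ``source_cols`` designates the candidate-source
    block; dropping it yields the marginal space used by the estimator, and
    surrogate generation permutes it among rows with similar remaining
    (target + conditioning) coordinates.  ``tau`` is the duration over which
    all required histories exist (the effective observation period used to
    normalise rate estimates).
    """

    X: np.ndarray
    U: np.ndarray
    columns: tuple
    source_cols: tuple
    tau: float
    spike_times: np.ndarray
    u_times: np.ndarray = None
    n_dropped_X: int = 0
    n_dropped_U: int = 0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.X.shape[1] != self.U.shape[1] or len(self.columns) != self.X.shape[1]:
            raise ValueError("X/U/columns disagree on column count")

    @property
    def n_x(self) -> int:
        return self.X.shape[0]

    @property
    def n_u(self) -> int:
        return self.U.shape[0]

    @property
    def marginal_cols(self) -> np.ndarray:
        mask = np.ones(self.X.shape[1], dtype=bool)
        mask[list(self.source_cols)] = False
        return np.flatnonzero(mask)

    def with_source_cols(self, cols) -> "SampleSet":
        cols = tuple(int(c) for c in cols)
        for c in cols:
            if not 0 <= c < self.X.shape[1]:
                raise ValueError("source column index out of range")
        return replace(self, source_cols=cols)

    def with_source_process(self, process_id) -> "SampleSet":
        cols = tuple(
            i for i, (pid, _lag) in enumerate(self.columns) if pid == process_id
        )
        if not cols:
            raise ValueError(f"no columns belong to process {process_id!r}")
        return self.with_source_cols(cols)


def history_embedding(train: SpikeTrain, t: float, depth: int):
    """Embedding of ``train``'s history at time ``t``, or None if too shallow.

    History is strictly pre-``t``: a spike at exactly ``t`` is excluded from
    its own history.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    vec, ok = embed_at_times(train.times, np.asarray([t], dtype=float), depth)
    return vec[0] if ok[0] else None


def embed_at_times(times: np.ndarray, eval_times: np.ndarray, depth: int):
    """Vectorised history embeddings at many evaluation times.

    Returns ``(matrix, valid)``: rows of ``matrix`` are only meaningful where
    ``valid`` is True (at least ``depth`` spikes strictly before the time).
    """
    eval_times = np.asarray(eval_times, dtype=np.float64)
    idx = np.searchsorted(times, eval_times, side="left")  # spikes strictly < t
    valid = idx >= depth
    out = np.zeros((eval_times.size, depth), dtype=np.float64)
    safe = np.where(valid, idx, depth)
    out[:, 0] = eval_times - times[safe - 1]
    for j in range(1, depth):
        out[:, j] = times[safe - j] - times[safe - j - 1]
    out[~valid] = np.nan
    return out, valid


def uniform_sample_times(t_start: float, t_end: float, n: int, rng) -> np.ndarray:
    """n i.i.d. Uniform(t_start, t_end) sample times, sorted."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    return np.sort(t_start + (t_end - t_start) * rng.random(n))


def spike_anchored_sample_times(
    target_train: SpikeTrain,
    half_width: float,
    n_per_spike: int,
    rng,
    t_start: float = -np.inf,
    t_end: float = np.inf,
) -> np.ndarray:
    """Sample times anchored at target spikes plus uniform noise.

    For recordings dominated by dense bursts, uniform sampling under-samples
    the regions of intense activity; anchoring each sample at an existing
    target spike (plus Uniform(-half_width, +half_width) noise) concentrates
    the reference distribution where the dynamics live.  Samples falling
    outside the observation window are dropped.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    if len(target_train) == 0:
        raise ValueError("target train is empty")
    base = np.repeat(target_train.times, n_per_spike)
    t = base + rng.uniform(-half_width, half_width, size=base.size)
    keep = (t >= t_start) & (t <= t_end)
    return np.sort(t[keep])


def _first_valid_time(recording: Recording, depths: dict) -> float:
    t0 = -np.inf
    for pid, d in depths.items():
        times = recording.train(pid).times
        if times.size < d:
            raise ValueError(
                f"insufficient history depth: process {pid!r} has "
                f"{times.size} spikes, needs {d}"
            )
        t0 = max(t0, times[d - 1])
    return t0


def assemble_sample_set(
    recording: Recording,
    target_id,
    spec: EmbeddingSpec,
    n_u: int,
    rng,
    sampling: str = "uniform",
    anchor_half_width: float = 0.08,
    anchor_per_spike: int = 20,
    min_samples: int = 10,
) -> SampleSet:
    """Build the X and U matrices for one estimate.

    X rows are built at every target spike at which *all* processes in the
    spec are embeddable; U rows likewise at random sample times (uniform over
    the window, or spike-anchored).  Sample points without sufficient history
    are dropped and counted.  ``tau`` is the window duration past the point
    where all required histories first exist.
    """
    depths = spec.depth_map(target_id)
    t_first = _first_valid_time(recording, depths)
    tau = recording.t_end - t_first
    if tau <= 0:
        raise ValueError("insufficient history depth: no valid observation period")

    target = recording.train(target_id)
    x_times = target.times[target.times > t_first]

    if sampling == "uniform":
        u_times = uniform_sample_times(recording.t_start, recording.t_end, n_u, rng)
    elif sampling == "anchored":
        per = max(1, int(round(n_u / max(1, len(target)))))
        u_times = spike_anchored_sample_times(
            target, anchor_half_width, per, rng, recording.t_start, recording.t_end
        )
    else:
        raise ValueError(f"unknown sampling mode {sampling!r}")

    columns, x_blocks, u_blocks = [], [], []
    x_valid = np.ones(x_times.size, dtype=bool)
    u_valid = np.ones(u_times.size, dtype=bool)
    for pid, d in depths.items():
        times = recording.train(pid).times
        xb, xv = embed_at_times(times, x_times, d)
        ub, uv = embed_at_times(times, u_times, d)
        x_valid &= xv
        u_valid &= uv
        x_blocks.append(xb)
        u_blocks.append(ub)
        columns.extend((pid, lag) for lag in range(1, d + 1))

    X = np.hstack(x_blocks)[x_valid]
    U = np.hstack(u_blocks)[u_valid]
    if X.shape[0] < min_samples:
        raise ValueError(
            f"insufficient history depth: only {X.shape[0]} valid target-spike "
            f"samples (need {min_samples})"
        )
    source_cols = tuple(
        i for i, (pid, _lag) in enumerate(columns) if pid in spec.source_depths
    )
    return SampleSet(
        X=X,
        U=U,
        columns=tuple(columns),
        source_cols=source_cols,
        tau=float(tau),
        spike_times=x_times[x_valid],
        u_times=u_times[u_valid],
        n_dropped_X=int(np.sum(~x_valid)),
        n_dropped_U=int(np.sum(~u_valid)),
    )
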