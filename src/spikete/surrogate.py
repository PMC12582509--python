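"""Null-model surrogates by local permutation, and significance testing.

The local-permutation scheme destroys the relationship between the candidate
source's history intervals and the occurrence of target spikes, while
retaining the relationship between the source intervals and the target /
conditioning intervals: each X row receives the source block of a row whose
remaining coordinates are close to its own.  Estimates on such surrogates
form the null population for empirical and normal-approximation p-values,
and for the familywise maximum-statistic test used when selecting parents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy import stats
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .embedding import SampleSet

__all__ = [
    "SurrogatePopulation",
    "local_permutation",
    "permutation_indices",
    "empirical_p",
    "normal_p",
    "max_statistic_p",
    "bias_correct",
]

# exact "k nearest not-yet-used" bookkeeping needs full sorted neighbour
# lists; above this row count a truncated list with random fallback is used
_EXACT_N = 512


@dataclass(frozen=True)
class SurrogatePopulation:
    """TE/AIS rates under the local-permutation null."""

    values: np.ndarray
    k_perm: int
    n_u_surrogates: int
    seed: int | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.size < 1:
            raise ValueError("surrogate population is empty")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite surrogate value")


@njit(cache=True)
def _assign_pool(nbrs, k_perm, order, u_choice, u_fallback, m):  # pragma: no cover
    """Donor assignment without replacement from a pool of m rows.

    Row i draws uniformly from the first k_perm not-yet-used entries of
    nbrs[i]; if none remain, uniformly from the whole unused pool.
    """
    n = order.size
    used = np.zeros(m, dtype=np.bool_)
    pool = np.arange(m)
    pool_pos = np.arange(m)
    pool_size = m
    donor = np.empty(n, dtype=np.int64)
    cand = np.empty(k_perm, dtype=np.int64)
    for ii in range(n):
        i = order[ii]
        cnt = 0
        for jj in range(nbrs.shape[1]):
            j = nbrs[i, jj]
            if j < 0:
                break
            if not used[j]:
                cand[cnt] = j
                cnt += 1
                if cnt == k_perm:
                    break
        if cnt > 0:
            pick = cand[int(u_choice[ii] * cnt)]
        else:
            pick = pool[int(u_fallback[ii] * pool_size)]
        donor[i] = pick
        used[pick] = True
        p = pool_pos[pick]
        last = pool[pool_size - 1]
        pool[p] = last
        pool_pos[last] = p
        pool_size -= 1
    return donor


def donor_assignment(nbr: np.ndarray, m: int, k_perm: int, rng) -> np.ndarray:
    """Without-replacement donor draw for each row from its neighbour list."""
    n = nbr.shape[0]
    if m < n:
        raise ValueError("donor pool smaller than the number of rows")
    return _assign_pool(
        np.ascontiguousarray(nbr, dtype=np.int64),
        k_perm,
        rng.permutation(n),
        rng.random(n),
        rng.random(n),
        m,
    )


@njit(cache=True)
def _assign(nbrs, k_perm, order, u_choice, u_fallback):  # pragma: no cover
    n = order.size
    used = np.zeros(n, dtype=np.bool_)
    pool = np.arange(n)
    pool_pos = np.arange(n)
    pool_size = n
    perm = np.empty(n, dtype=np.int64)
    cand = np.empty(k_perm, dtype=np.int64)
    for ii in range(n):
        i = order[ii]
        cnt = 0
        for jj in range(nbrs.shape[1]):
            j = nbrs[i, jj]
            if j < 0:
                break
            if not used[j]:
                cand[cnt] = j
                cnt += 1
                if cnt == k_perm:
                    break
        if cnt > 0:
            pick = cand[int(u_choice[ii] * cnt)]
        else:
            pick = pool[int(u_fallback[ii] * pool_size)]
        perm[i] = pick
        used[pick] = True
        p = pool_pos[pick]
        last = pool[pool_size - 1]
        pool[p] = last
        pool_pos[last] = p
        pool_size -= 1
    return perm


def permutation_indices(subspace: np.ndarray, k_perm: int, rng, nbrs=None) -> np.ndarray:
    """Draw one local permutation of row indices.

    Rows are processed in a seeded random order; each receives a donor drawn
    uniformly from its ``k_perm`` nearest not-yet-used rows in ``subspace``
    (Chebyshev norm; the row itself counts as a distance-zero candidate).
    With ``k_perm >= n - 1`` every unused row is always a candidate, so the
    scheme reduces to — and is implemented as — a uniform random permutation.
    """
    n = subspace.shape[0]
    if k_perm < 1:
        raise ValueError("k_perm must be >= 1")
    if k_perm >= n:
        warnings.warn("k_perm >= row count; falling back to a global permutation")
        return rng.permutation(n)
    if k_perm >= n - 1:
        return rng.permutation(n)
    if nbrs is None:
        nbrs = neighbour_lists(subspace, k_perm)
    return _assign(
        nbrs,
        k_perm,
        rng.permutation(n),
        rng.random(n),
        rng.random(n),
    )


def neighbour_lists(subspace: np.ndarray, k_perm: int) -> np.ndarray:
    """Sorted candidate-donor lists per row (self included, -1 padded)."""
    n = subspace.shape[0]
    if subspace.shape[1] == 0:
        # zero-dimensional subspace: all rows equidistant; index order
        return np.tile(np.arange(n, dtype=np.int64), (n, 1))
    if n <= _EXACT_N:
        d = cdist(subspace, subspace, metric="chebyshev")
        return np.argsort(d, axis=1, kind="stable").astype(np.int64)
    width = min(n, 4 * k_perm)
    tree = cKDTree(subspace)
    _, idx = tree.query(subspace, k=width, p=np.inf)
    return np.asarray(idx, dtype=np.int64)


def local_permutation(samples: SampleSet, k_perm: int, rng) -> SampleSet:
    """Permute the source block of X among rows with similar other coordinates."""
    if not samples.source_cols:
        raise ValueError("sample set has no designated source block")
    src = list(samples.source_cols)
    perm = permutation_indices(samples.X[:, samples.marginal_cols], k_perm, rng)
    X = samples.X.copy()
    X[:, src] = samples.X[np.ix_(perm, src)]
    return replace(samples, X=X)


def empirical_p(original: float, surrogates) -> float:
    """Proportion of surrogate values >= the original estimate (ties count)."""
    v = _values(surrogates)
    return float(np.count_nonzero(v >= original)) / v.size


def normal_p(original: float, surrogates) -> float:
    """Upper-tail p under a normal fitted to the surrogates (sd with n-1).

    Fitting a normal lets the test resolve p-values far below 1/n_surrogates,
    which the empirical proportion cannot.
    """
    v = _values(surrogates)
    if v.size < 2:
        raise ValueError("need >= 2 surrogates for a normal approximation")
    sd = float(np.std(v, ddof=1))
    if sd == 0:
        raise ValueError("zero-variance surrogate population")
    return float(stats.norm.sf(original, loc=float(np.mean(v)), scale=sd))


def max_statistic_p(original_per_candidate, surrogate_matrix):
    """Familywise test of the best candidate against per-surrogate maxima.

    ``surrogate_matrix`` has one row per candidate and one column per
    surrogate; originals and surrogates are expected bias-corrected.  The
    null population is the column-wise maximum (replicating, under the null,
    the selection of the best candidate), so the test controls the
    familywise error rate of the selection step.
    """
    orig = np.asarray(original_per_candidate, dtype=np.float64)
    surr = np.asarray(surrogate_matrix, dtype=np.float64)
    if surr.ndim != 2 or surr.shape[0] != orig.size:
        raise ValueError("surrogate matrix shape does not match candidates")
    winner = int(np.argmax(orig))  # ties -> lowest index
    maxima = surr.max(axis=0)
    return winner, empirical_p(orig[winner], maxima)


def bias_correct(original: float, surrogates):
    """Shift the original and surrogates by minus the surrogate mean."""
    v = _values(surrogates)
    m = float(np.mean(v))
    return original - m, v - m


def _values(surrogates) -> np.ndarray:
    if isinstance(surrogates, SurrogatePopulation):
        return surrogates.values
    v = np.asarray(surrogates, dtype=np.float64)
    if v.size == 0:
        raise ValueError("surrogate population is empty")
    return v
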