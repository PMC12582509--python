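# Methods

## Problem and quantities

`spikete` infers *effective networks* from event-timestamp data: for each
target process it seeks the smallest set of source processes whose histories
jointly explain the target's spiking. The central quantity is the
continuous-time transfer-entropy (TE) rate

    TE_rate(Y -> X | Z) = (1/tau) * sum_i ln [ lambda(x_i | x<, z<, y<) /
                                               lambda(x_i | x<, z<) ]

a sum over the N_X spikes x_i of the target during the observation period
tau of log ratios of the target's instantaneous rate with and without the
source history, in nats per second. Histories are represented as
inter-spike-interval vectors — time since the most recent spike strictly
before the evaluation point, followed by the preceding intervals, most
recent first — which keeps the state space low-dimensional at full timing
precision and is what makes conditioning sets of useful size feasible.

The conditional active-information-storage (AIS) increment — the mutual
information between the oldest target interval considered and the target's
spiking, given the more recent intervals — is the same computation with
that oldest interval playing the role of the source block; it decides how
many target intervals to embed.

## Estimator

Each log intensity ratio is estimated as the difference of two
k-nearest-neighbour Kullback–Leibler divergence estimates between the
spike-conditioned history sample `X` (embeddings at target spikes) and a
time-uniform reference sample `U` (embeddings at N_U random times): one
estimate in the joint space (with the source block), one in the marginal
space (without it). The per-point core is `d * ln(nu_i / rho_i)` with
`rho_i` the k-th neighbour distance within `X` and `nu_i` the k-th
neighbour distance into `U`, Chebyshev norm; the `ln(m/(n-1))` reference
constants cancel between the two spaces except when the marginal space is
empty (the depth-1 AIS increment), where they are kept explicitly with the
exact per-row reference counts.

Defaults (simulated-data settings): `k_global = 4`, `k_perm = 20`,
`N_U = 20 N_X`, `N_U,surrogates = 20 N_X`, `n_surrogates = 100`. Dense
recordings benefit from a larger `k_global` (lower variance) and from
spike-anchored reference sampling (`sampling="anchored"`, ±80 ms around
target spikes), which concentrates the reference sample where burst
dynamics live.

### Temporal-coherence exclusion

`X` and `U` come from one realisation, so samples taken at nearby times are
*coherent*: every lag-1 coordinate of one is the other's shifted by the
elapsed time, while deeper intervals coincide, until a spike of any embedded
process intervenes. Coherent pairs act as artificial nearest neighbours and
bias the estimator differently for original and resampled data (measured on
independent 10 Hz Poisson pairs: about −1.5 nats/s at 60 s, enough to ruin
the significance test). All neighbour searches therefore skip candidates
whose sample times lie within a window `W` of any of the query row's anchor
times, two-sided; `W` is twice the median k-th-neighbour radius — beyond
that scale a coherent candidate is no closer than a generic one, so the
window's exact width stops mattering (verified: calibration is flat in the
multiplier over 1–4).

### Surrogates

The null hypothesis is that the target's instantaneous rate does not depend
on the source history given the remaining (target + conditioning)
histories. Under it, the source block of a spike-conditioned sample is
distributed as the source block at a non-spike time with the same remaining
histories. Surrogates therefore redraw each `X` row's source block from a
donor drawn uniformly among the row's `k_perm` nearest neighbours — in the
marginal subspace — within a dedicated surrogate reference sample
(`N_U,surrogates` fresh embeddings per estimate), without replacement; all
surrogate searches run against the same `U` as the original's, and each
surrogate row carries its donor's draw time as a second exclusion anchor.
The original estimate is given a *phantom* donor anchor drawn by the same
procedure (its source block unused), so original and surrogate exclusion
geometries are statistically identical and only the provenance of the
source block differs.

Two simpler schemes fail and are retained only as documentation of the
design space: permuting source blocks **among the X rows** preserves the
source-history distribution *conditioned on spiking* and therefore does not
destroy the dependence under test (surrogate TE tracks the original on
strongly coupled pairs; power ≈ 0); drawing donors from `U` while searching
the same `U` leaves each donor row as a near-duplicate of its recipient
(p ≈ 0 under the null).

Calibration: on independent Poisson pairs (10 Hz, 60 s) the empirical
p-values are uniform (KS) with false-positive rate ≤ 0.05 at α = 0.05, and
the same holds on held-out nulls (5 and 30 Hz pairs, Gamma-renewal targets,
storage increments of memoryless processes, and a conditional null — an
unconnected bystander tested given the target's true parent). A residual
conservative tilt of roughly +0.1–0.2 surrogate standard deviations remains
in some regimes; it costs a little power and never inflates the error rate.

Significance: `p_empirical` is the proportion of surrogate rates ≥ the
original (ties count; 0 is attainable), `p_normal` the upper tail of a
normal fitted to the surrogates (useful below the 1/n_surrogates
resolution). Bias correction subtracts the surrogate mean from the original
and the surrogates. When a candidate is *selected* among several, the
maximum-statistic test compares the winner against the per-surrogate maxima
across candidates, which controls the familywise error of the selection.

## Greedy algorithm

Per target: (1) embed at least one target interval, growing the depth while
the AIS increment of the next interval is significant (plain empirical
test, α as everywhere, capped at `max_target_depth = 5`); (2) rounds of
candidate addition — each source's next unadded interval, most recent
first, at most one interval per source per round and `max_source_intervals
= 3` per source — keeping the argmax of bias-corrected conditional TE if it
passes the maximum-statistic test; (3) pruning — re-estimate each retained
source's *last* interval given everything else, plain empirical test, fresh
surrogates per round, removing the largest-p interval while p > α. Ties in
the argmax break to the lowest unit index. Targets are independent. TE
calculations per target scale as O(N_proc · d · S) with S = n_surrogates.

The pairwise baseline tests every ordered pair with one source interval and
no conditioning, retaining the full p-value matrix for ROC sweeps (pruning
excluded; edge kept when p ≤ α).

## Ground-truth simulator

Leaky integrate-and-fire neurons, `tau dV/dt = (V0 − V) + R_m I_syn`, spike
threshold 40 mV, reset 0, hard refractory 2 ms (the refractory length is
not fixed by the model specification; 2 ms is this package's default and is
recorded in metadata). Alpha synapses `I(t) = a * sum_s ((t−t_s)/tau_syn)
exp(−(t−t_s)/tau_syn)`, tau = tau_syn = 20 ms; excitatory strength
+20 mA, inhibitory −g·20 mA; every neuron receives exactly `n_exc`
excitatory and `n_inh` inhibitory afferents drawn uniformly without
replacement, plus an independent stimulus train (Poisson, regular, or
regular-with-Gaussian-jitter; per-neuron rates optionally drawn from a
normal law) through the same kernel. Integration is exponential-Euler at
dt = 0.1 ms: the alpha kernel is the impulse response of a two-state linear
filter and both the filter and the membrane decay use their exact per-step
exponential maps; crossing times are recorded at step resolution, so
recordings are jittered by ±dt/2 before estimation (interval grids
otherwise leak into the neighbour searches — the same procedure applies to
acquisition-clock-quantised recordings, e.g. ±20 µs for a 40 µs grid).

One global current scale, `drive_scale = 1.15`, multiplies all synaptic and
stimulus strengths. At the nominal strengths the 200 Hz/6 mA stimulus
delivers a mean drive of 24 mV against the 40 mV threshold and the cascade
branching ratio stays below one: the network never leaves a stimulus-driven
~0.1 Hz floor and the inhibition ratio g has no effect on the dynamics. The
15% rescaling is the smallest calibration we found that places all three
synchrony presets (g = 1, 1.5, 3) in the sustained-activity region, with
the population Fano factor (10 ms bins) strictly decreasing in g across
connectivity seeds, mean rates of roughly 2–30 Hz, and higher rates at
g = 1 than g = 3.

Isolated two/three-neuron motifs lack the recurrent pool that carries part
of the drive in full networks; the motif fixtures use an 8 mA stimulus so
the motif fires at 8–14 Hz, where single-synapse coupling is reliably
detectable.

## What the synthetic data does and does not show

The generators cover stationary Poisson/renewal processes and
fully-observed LIF networks with known connectivity — the idealised
conditions under which an effective network can be expected to match the
causal one. They do not emulate bursty culture-like population events,
non-stationarity over hours, sub-sampled populations, or spike-sorting
artefacts; passing these tests shows calibration and recovery under the
stated conditions, not performance on such data (for dense bursty
recordings the anchored sampling mode and a larger `k_global` are the
intended settings).

Validation problem sizes are chosen for single-workstation runtimes: null
calibration uses 10 Hz/60 s pairs (~600 target spikes) over 100+ runs;
chain recovery uses 3-neuron motifs at 1000 target spikes; network recovery
uses 6–12 neuron nets with class in-degrees 2+1 at 100–1000 target spikes.
Because the greedy
significance sweep is capped at α = 0.75 and small-scale recall tops out
well below one, greedy ROC curves never approach (1,1); greedy and pairwise
curves are therefore compared by partial AUC over the false-positive range
the greedy sweep attains, where the full-scale phenomenon (the multivariate
curve sitting far above the pairwise one) is the stable signature.
Network fixtures reject connectivity draws whose simulation cannot reach
the per-train spike quota with bounded rate heterogeneity (a rare draw
leaves a neuron nearly silent under strong convergent inhibition).
Small dense networks are *harder* for precision than the larger sparse
networks they stand in for: with few nodes a large fraction of ordered
pairs are confounded by two-hop paths and shared parents, and while recall
is partial the unrecovered mediators leave indirect paths unexplained, so a
handful of false positives can dominate the precision denominator.
Precision rises with the number of target spikes together with recall, but
at these scales it can sit below the ~0.9 that larger sparse networks
reach.

## Numerical choices

- Chebyshev norm throughout (subspace distances consistent); Euclidean is
  available via `norm="euclidean"` (slow path).
- Duplicate sample rows (zero k-th neighbour distance) are broken by
  seeded Uniform(−1e−10, 1e−10) noise on the embedding coordinates,
  applied only when duplicates or zero-variance columns are detected.
- All randomness flows from a single `numpy.random.Generator`; identical
  seeds and inputs give identical outputs, including byte-identical
  inferred networks.
- The joint-space searches use an exact fast path (shared marginal-distance
  geometry plus per-surrogate source distances, with candidate-list bounds
  verified row by row and repaired through tree searches) that returns
  bit-identical results to the tree-based implementation; estimates with
  more than 2500 target spikes fall back to the tree path.
- Time-scaling covariance is exact: scaling all timestamps by a power of
  two leaves the per-spike terms bit-identical and divides the rate by the
  same factor.

## Known limitations

- The kNN divergence core carries the usual finite-sample bias of
  nearest-neighbour estimators (boundary effects are visible for
  exponential laws, on the order of +0.1 nats at n = 2000 with k = 4);
  the surrogate-based bias correction and rank tests are unaffected, but
  raw divergence estimates should not be read to better than that.
- The empirical p-distribution carries a mild conservative tilt in some
  regimes (mean ≈ 0.55), costing power, and a slight overdispersion at the
  extremes from the shared reference sample across a test's surrogates.
- Runtime is dominated by the per-surrogate neighbour searches; a full TE
  test at 1000 target spikes takes on the order of a second, so
  network-scale experiments are minutes to tens of minutes.
- The estimator assumes stationarity within the analysed window; windowing
  (`extract_window`) and the minimum-spike filter are the intended
  preprocessing for long non-stationary recordings.
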