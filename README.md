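# spikete

Effective-network inference from spike trains (or any event-timestamp data)
via continuous-time transfer entropy.

Given simultaneously recorded event processes, `spikete` finds, for each
target process, the smallest set of source processes whose past activity
jointly explains the target's spiking. The central statistic is the
continuous-time transfer-entropy rate

    TE(Y -> X | Z) = lim (1/tau) * sum_i  ln [ lambda(x_i | x<, z<, y<)
                                             / lambda(x_i | x<, z<) ]

— a sum over the target's spikes x_i of log ratios of history-conditional
firing rates, in nats/s, with histories represented as inter-spike-interval
vectors and the conditional rates estimated by k-nearest-neighbour searches
(no time binning, full timing precision). Edges are selected greedily per
target: the number of target history intervals is chosen by conditional
active-information-storage increments, candidate source intervals are added
while the best candidate passes a familywise (maximum-statistic) surrogate
test, and a final pruning step removes sources made redundant by later
additions. Surrogates are generated by resampling source histories from the
time-uniform conditional given the remaining histories, which preserves
cross-history correlations while destroying the source-to-spiking
dependence under test.

The package also contains the validation stack: a leaky integrate-and-fire
network simulator with alpha synapses and configurable stimuli (known
ground-truth connectivity, tunable synchrony via the inhibition ratio g),
precision/recall and ROC scoring against ground truth, and network-summary
analyses (degrees, between-day degree correlations with Fisher combination,
distance-resolved edge proportions for electrode layouts).

Intended users: neuroscientists and complex-systems researchers analysing
spike trains from simulations, multi-electrode arrays, or any other
event-based recordings.

## Worked example

```python
import numpy as np
import spikete as sp
from spikete import experiments as ex

# a 3-neuron circuit: 0 -> 1 excitatory, 2 unconnected; ~1000 spikes/unit
rec, truth = ex.lif_chain_recording(seed=1, n_target=1000)

est = sp.conditional_te_rate(rec, "1", "0", target_depth=2,
                             rng=np.random.default_rng(0))
print(f"TE(0->1) = {est.bias_corrected_rate:.2f} nats/s, "
      f"p = {est.p_empirical}")

net = sp.GreedyNetworkInference(random_state=0).fit(rec)
print("parents of 1:", net.parent_sets_["1"].source_intervals)
```

prints

```
TE(0->1) = 2.24 nats/s, p = 0.0
parents of 1: {'0': 1}
```

The bias-corrected TE of the true synapse is strongly positive and none of
its 100 local surrogates reaches it (p = 0.0); the greedy inference for
target `1` keeps exactly one interval of source `0` and excludes the
bystander `2`.

The same pipeline runs from the shell:

```
spikete simulate out/ --g 3 --target-spikes 500 --seed 1
spikete infer out/spikes.tsv net/ --alpha 0.05 --seed 1
spikete estimate out/spikes.tsv --target 1 --source 0 --seed 1
```

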