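# dynconn

Dynamic functional connectomes from multi-animal neural activity traces.

Anatomical wiring is static, but function is not: during an experiment,
different groups of neurons become co-active in different epochs — when a
stimulus is applied, when a behavior starts. `dynconn` infers these
*transient functional circuits* from fluorescence-like activity traces
recorded in several animals under a shared stimulus protocol, with no
supervision and no anatomical prior. The pipeline has three stages:

1. **Differential affinity.** For every neuron pair (i, j), animal w and
   frame t, a local similarity

   a_ij(t) = [min(|ẋ_i|, |ẋ_j|) / max(|ẋ_i|, |ẋ_j|)] · (1 − e^(−max(|ẋ_i|, |ẋ_j|)/κ)),

   evaluated only where both smoothed derivatives ẋ keep a constant sign
   (monotone segments), and 0 elsewhere. Using *absolute* derivatives makes
   the measure blind to sign, so mutually inhibiting neurons with opposite
   excursions still score high; the exponential gate suppresses
   coincidences between near-flat traces.

2. **Non-negative tensor factorization.** The affinities form a
   TIME × ANIMALS × PAIRS tensor (pairs = vectorized upper triangle,
   n(n−1)/2). A rank-R canonical polyadic decomposition with non-negative
   factors, fitted by multi-restart HALS (hierarchical alternating least
   squares, with EM-style imputation for unobserved neurons), yields R
   components (f_t, f_w, f_a): *when* a pairwise-affinity pattern occurs,
   in *which animals*, and between *which pairs*.

3. **Weighted-SBM communities.** Each affinity factor f_a, reshaped to a
   symmetric matrix, is a weighted graph on neurons. A weighted stochastic
   block model — microcanonical adjacency counts per block pair, exponential
   edge weights with the rate integrated out under a conjugate Gamma prior,
   and nested uniform priors on the partition — is fitted by minimizing the
   description length L = −ln P(G | θ, c) − ln P(θ, c) with a seeded
   multi-flip Metropolis sampler (single-node moves, merge/split moves,
   annealing, greedy polish). The number of communities is inferred, not
   fixed.

The package also ships the evaluation harness used to justify the
community-detection choice: a weighted LFR-style benchmark generator with
planted communities, normalized mutual information (NMI) scoring, and a
greedy-modularity baseline — plus a synthetic multi-animal trace generator
with planted circuits so the whole pipeline is testable end to end without
any dataset.

## Worked example

Two circuits of four neurons each are planted in five simulated animals:
neurons 0–3 co-active during frames [60, 180), neurons 5–8 during
[230, 350), observation noise at 5 % of the excursion amplitude, and one
anti-correlated member per circuit.

```python
import numpy as np, dynconn as dc

cfg = dc.PipelineConfig(
    simulate={
        "n_neurons": 12, "n_animals": 5, "n_timepoints": 400,
        "circuits": [
            {"members": [0, 1, 2, 3], "window": [60, 180]},
            {"members": [5, 6, 7, 8], "window": [230, 350]},
        ],
        "noise_sd": 0.05, "baseline_drift_sd": 0.0,
    },
    rank=2, n_restarts=5, zero_band=0.03, kappa=0.02, w_min=0.1, seed=7,
)
result = dc.run_pipeline(cfg)
model = result.cp.model_
print("lambdas:", np.round(model.lambdas, 2))
for r, part in enumerate(result.partitions):
    peak = int(np.argmax(model.temporal[:, r]))
    print(f"component {r}: temporal peak at frame {peak}, "
          f"{part.n_communities} communities, dl={part.dl:.2f}")
scores = dc.evaluate_recovery(result)
for m in scores["matches"]:
    print(f"component {m['component']} <-> circuit {m['circuit']}: "
          f"window corr {m['temporal_corr']:.3f}, membership NMI {m['membership_nmi']:.3f}")
```

prints

```
lambdas: [10.37  4.83]
component 0: temporal peak at frame 179, 2 communities, dl=16.51
component 1: temporal peak at frame 346, 2 communities, dl=16.51
component 0 <-> circuit 0: window corr 0.907, membership NMI 1.000
component 1 <-> circuit 1: window corr 0.947, membership NMI 1.000
```

Each tensor component locked onto one planted window (temporal peaks at
frames 179 and 346, inside [60, 180) and [230, 350)), and the SBM split
each component's graph into exactly {circuit members} vs {everything
else} — membership NMI 1.0 against the planted ground truth. The
description length (16.51 nats) is the model-selection score: the
single-block alternative for the same graphs costs 22.90 nats, so the
two-community structure is decisively preferred.

The same run is available from the shell:

```bash
dynconn pipeline --config cfg.json --outdir out/   # all three stages
dynconn simulate / affinity / factorize / communities / benchmark  # stage-wise
```

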