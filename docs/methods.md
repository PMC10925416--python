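# Methods

This note documents the models implemented in `dynconn`, the parameters
that matter, the synthetic data used to validate them, and the known
limitations. Nothing here is an empirical claim beyond what the test
suite and `scripts/acceptance.py` compute.

## 1. Local differential affinity

**Model.** Instantaneous trace values are not informative on their own —
two silent neurons are trivially "similar", and two neurons that reach
the same level minutes apart are unlikely to interact. The affinity is
therefore built from rates of monotonic change. Traces are smoothed with
a Gaussian kernel (reflective boundaries) and differentiated by central
differences; both operations are linear. For each trace, *monotone
segments* are maximal frame runs where the smoothed derivative keeps one
sign, after zeroing magnitudes below `zero_band` and discarding runs
shorter than `min_duration`. For a pair (i, j) at frame t inside a
monotone segment of *both* traces,

    a_ij(t) = min(|d_i|,|d_j|) / max(|d_i|,|d_j|) · (1 − exp(−max(|d_i|,|d_j|)/κ)),

and a_ij(t) = 0 elsewhere. Properties relied on downstream and verified
by tests: boundedness in [0, 1], exact symmetry in (i, j), exact
invariance under negating either trace (absolute derivatives — inhibitory
partners score as high as excitatory ones), scale covariance (rescaling
both traces and κ together changes nothing), and suppression of
near-flat coincidences by the gate. The segment requirement enforces
strict temporal coincidence; no tolerance for offset excursions is
applied.

**Parameters.**

| parameter | units | default | role |
|---|---|---|---|
| `sigma` | s | 4 samples | derivative smoothing scale |
| `zero_band` | activity/s | 5th pct of \|d\| per animal | "flat" threshold for segment signs |
| `min_duration` | s | 3 samples | minimum credible monotone run |
| `kappa` | activity/s | median \|d\| | gate scale; derivative at which the gate reaches 1 − 1/e |

The data-driven defaults are deliberately permissive and suit exploratory
use. When the noise scale is known — as in the synthetic studies, where
the generator's noise level is chosen — the scales should be set
explicitly; the study configurations use `zero_band = 0.03` (about 5× the
median noise derivative, the usual robust-threshold rule), `kappa = 0.02`
(well below circuit derivative magnitudes, so the gate saturates on real
excursions), and `w_min = 0.1` when thresholding factor matrices into
graphs. Missing neurons propagate as a mask — affinities involving them
are *missing*, not zero — so the factorization can interpolate them.

## 2. Affinity tensor and non-negative CP decomposition

The per-frame affinity matrices of all animals are arranged as a
T × W × P tensor, P = n(n−1)/2 (upper-triangular vectorization,
lexicographic (i, j), i < j; symmetric matrices carry no information in
the lower triangle). The tensor is approximated by a rank-R
non-negative canonical polyadic model, minimizing half the squared error
over observed entries. Fitting is HALS: cyclic closed-form updates of
one factor column at a time with projection to the non-negative orthant,
using matricized-tensor-times-Khatri-Rao products. Masked entries are
imputed with the current reconstruction before every sweep (EM-style),
which provably keeps the observed-entry objective non-increasing; tests
assert monotonicity to 1e-10 slack and bit-level independence of the fit
from values stored under the mask.

Numerical choices: random uniform initialization scaled to the tensor's
mean, seeded; `n_restarts = 10` (best objective wins), `tol = 1e-7`
relative objective change, `max_iter = 500`. Columns with a vanishing
Gram diagonal are zeroed (degenerate components are allowed to die). The
fitted model is canonicalized — affinity-factor columns unit-norm with
the scale folded into λ_r, components sorted by λ descending — because CP
models are only identified up to permutation and scale. An all-zero
tensor yields the all-zero model with objective 0.

Rank selection is diagnostic, not automatic: `select_rank` reports the
best objective and a restart-stability score (mean pairwise factor
congruence across restarts, Hungarian-matched cosine products over the
three modes). A planted rank is markedly more stable than an overfit
one; tests assert this on planted tensors.

## 3. Weighted-SBM community detection

An affinity factor reshaped to a symmetric matrix is a weighted graph on
neurons (entries below `w_min` dropped; `w_min = 0` by default —
sparsification is an explicit user choice). Communities are inferred
with a single-level weighted stochastic block model selected by minimum
description length, L = −ln P(G|θ̂,c) − ln P(θ̂,c), with per block pair
(r, s), all in nats:

* **adjacency** — microcanonical placement count ln C(N_rs, e_rs) over
  the N_rs dyads (Stirling-equivalent to a Bernoulli likelihood at the
  MLE density), plus one global uniform prior over how the E edges
  distribute among the B(B+1)/2 block pairs,
  ln C(B(B+1)/2 + E − 1, E). The global multiset prior, rather than a
  per-pair cost, is what keeps the model calibrated at both extremes: it
  vanishes for one block and explodes for the all-singleton partition,
  whose saturated adjacency term would otherwise cost nothing.
* **weights** — edge weights in (0, 1] are modeled per block pair as
  exponential with the rate integrated out under a Gamma(1, 1) conjugate
  prior: marginal Γ(1+e_rs)/(1+s_rs)^(1+e_rs) for weight sum s_rs. The
  weight parameters therefore carry no plug-in cost. The exponential
  family was chosen for its exact closed-form marginal; a sharper family
  could be substituted behind `description_length` without touching the
  sampler.
* **partition prior** — uniform over the number of groups C, uniform over
  compositions of n into C sizes, uniform over labelings given sizes.

This makes C an inference output: extra groups must buy their prior cost
with likelihood, which is also what protects against grouping noise —
on weight-shuffled null graphs (same topology, permuted weights) the
inferred C does not exceed the structured graph's, a property the tests
check.

**Sampler.** Seeded Metropolis over labelings: 90 % single-node moves
(proposed toward a random neighbor's block with probability 0.8,
otherwise uniform over existing blocks plus a fresh one), 10 % multi-flip
moves (merge two blocks, or randomly bisect one). A geometric inverse-
temperature ramp β: 1 → 5 runs over `burnin + sweeps` sweeps of n
proposals; label samples collected after burn-in give per-node marginal
label frequencies (approximate model averaging — the proposal asymmetry
is not Hastings-corrected, so the sampler is used as a seeded stochastic
optimizer with approximate marginals, which is all the package's claims
require). The run ends with a deterministic greedy β → ∞ polish (best
single-node moves, then best merges, to convergence) from five starts:
the best state visited, the final chain state, singletons, the
connected components, and a single block. The multiple starts matter:
the description-length landscape has genuine valleys — e.g. for a small
clique among isolated nodes, no pairwise merge from singletons and no
single-node exit from one block improves L, yet the two-block optimum is
far better — and the component/singleton starts cross them
deterministically. Every proposal evaluates candidate sufficient
statistics (n_r, e_rs, s_rs) built incrementally and commits only on
acceptance; `validate=True` re-derives the statistics and L from scratch
after each accepted move and asserts agreement to 1e-9. Equal-L states
resolve to the first-encountered, canonically relabeled (first-occurrence
order) labeling, making results reproducible bit for bit under a fixed
seed. Defaults: 200 burn-in + 800 sampling sweeps.

Exhaustive enumeration over all set partitions (`exhaustive_minimum`,
n ≤ 12) provides the exact optimum for validation; on random weighted
graphs with n ≤ 8 the sampler matches it essentially always (20/20 in
the acceptance battery, and never below it).

## 4. Synthetic data

**Trace generator.** Emulates stimulus-locked multi-animal recordings: a
shared time axis, and planted circuits — member sets, half-open active
windows, participating animals, per-member polarity (at least one
negative member by default, to exercise sign invariance). During its
window, a circuit's members within one animal follow *exactly* the same
latent drive, scaled by amplitude × polarity on top of a baseline frozen
for the window's duration (so noise-free member traces are exact affine
copies); the drive realization differs across animals, emulating
individually varying responses to the same stimulus. The drive is a
jittered piecewise-linear ramp profile: random levels in [0, 1] with a
minimum step of 0.3 and segment durations of 3.5–7 s, so the slope stays
bounded away from zero and monotone segments tile the window — after
smoothing, turning points are the only dead frames. Outside windows,
neurons follow independent smoothed drift (`baseline_drift_sd`) plus
white observation noise (`noise_sd`). Defaults: dt = 0.25 s,
noise_sd = 0.05 (5 % of the unit amplitude).

What it does *not* emulate: calcium indicator kinetics (no asymmetric
rise/decay), motion and imaging artifacts, missing-frame dropouts,
inter-animal neuron misidentification, or overlapping circuits sharing
members in time (allowed but only flagged). Passing tests therefore
demonstrate correct recovery of planted co-excursion structure under
white noise — not robustness to every artifact of real recordings.

**File formats.** Per-animal CSV (rows = time, first column `time`,
neuron IDs as headers; absent columns = unobserved neurons) plus a JSON
manifest (`dt`, animal list, missing lists). Round-trips are exact to
double precision (`%.17g`).

**Benchmark generator.** Weighted LFR-style networks: truncated
power-law degrees (exponent `tau1`, lower cutoff solved so the mean
matches `avg_deg`), power-law community sizes (`tau2`) fitted to n,
capacity-aware community assignment, and rejection-based configuration-
model wiring (100 retries per stub, leftovers shed) with each node
placing a fraction `mu_topo` of its degree across communities. Weights
are Beta-distributed (concentration 10) with mean 1 − `mu_w` within and
`mu_w` between communities, clipped to (0, 1]. The default grid is nine
types varying mu_topo ∈ {0.05, 0.2, 0.4} × mu_w ∈ {0.1, 0.3, 0.5} with
two community-size regimes, at n = 60 — sizes chosen so the full
comparison (2 methods × 9 types × 10 instances) runs in minutes on one
CPU. The realized inter-community edge fraction is recorded per
instance; at n = 500 it tracks the requested mu_topo within ±0.05.

## 5. Evaluation conventions

NMI uses plug-in mutual information computed as H(p) + H(q) − H(p, q)
(exactly symmetric, exactly 1 for identical partitions) normalized by
the arithmetic mean of the entropies; 0·ln 0 = 0, and two single-cluster
partitions agree perfectly by convention. The greedy-modularity baseline
is the standard CNM agglomeration on weighted modularity (networkx),
with deterministic label extraction. End-to-end recovery matches tensor
components to planted circuits by temporal-factor/window-indicator
correlation (Hungarian assignment) and scores each matched component's
partition against the circuit's binary membership.

## 6. Known limitations

* **No degree correction.** The SBM models block-pair densities only; on
  graphs with strong degree heterogeneity inside communities (power-law
  LFR), the description length can genuinely favor splitting hubs from
  leaves within a planted community. On the benchmark this costs the SBM
  a few hundredths of mean NMI on otherwise easy networks, and the
  modularity baseline — which has no significance control and is very
  strong on small, clearly modular graphs — wins several network types;
  the SBM's advantage is confined to the weight-dominated regimes. A
  degree-corrected block model is the standard remedy and a natural
  extension.
* **Single level.** The model is a flat SBM (with an optional view of
  communities-of-communities via re-running on the block graph, not a
  full nested hierarchy with matched priors). At n = 60 with communities
  of size ~8–10 and 40 % mixing, the flat model sits at its detection
  limit and prefers one block — verified by direct description-length
  evaluation, not a sampler artifact.
* **Exponential weight marginal.** Weights concentrated near a high mean
  (e.g. 0.9) are poorly discriminated by an exponential family; most of
  the benchmark signal at high topological mixing is carried by weights,
  which caps the flat model's gain there.
* **Strict coincidence.** The affinity requires monotone segments to
  overlap at the same frame; systematically lagged interactions are
  invisible by design (no cross-correlation at lag).
* **Sampler exactness.** Posterior marginals are approximate (annealed,
  non-Hastings-corrected proposals); only the minimum-description-length
  state and its reproducibility are treated as exact claims.
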