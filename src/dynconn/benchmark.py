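"""Weighted-network benchmark: LFR-style generators, NMI, baselines.

Community-detection engines can only be compared on networks whose true
communities are known, so the evaluation protocol is: (i) generate
synthetic weighted networks with planted communities following the
Lancichinetti-Fortunato-Radicchi recipe (power-law degrees, power-law
community sizes, a topological mixing fraction ``mu_topo`` controlling
the share of inter-community edges, and a weight mixing parameter
``mu_w`` controlling how much larger within-community weights are than
between-community ones); (ii) score each method's partition against the
planted one with normalized mutual information; (iii) average over
seeded instances of each network type.

The wiring is a rejection-based configuration model: each node splits
its degree into within- and between-community stubs, stubs are paired
uniformly, and self-edges, duplicate edges and (for between stubs)
same-community pairs are rejected with a bounded retry budget, after
which leftover stubs are dropped.  Weights are Beta-distributed with
mean ``1 - mu_w`` within and ``mu_w`` between communities, clipped to
(0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._util import derive_seed
from .communities import Partition, WeightedGraph, mcmc_partition


@dataclass(frozen=True)
class LFRSpec:
    n: int = 60
    tau1: float = 2.5  # degree power-law exponent
    tau2: float = 1.5  # community-size power-law exponent
    mu_topo: float = 0.1  # fraction of each node's degree across communities
    mu_w: float = 0.1  # weight mixing: between-community mean weight
    avg_deg: float = 8.0
    max_deg: int = 20
    min_comm: int = 10
    max_comm: int = 25
    weight_concentration: float = 10.0  # Beta concentration for edge weights
    seed: int = 0
    name: str = ""

    def validate(self) -> None:
        if not (0.0 <= self.mu_topo <= 1.0):
            raise ValueError("mu_topo must be in [0, 1]")
        if not (0.0 <= self.mu_w <= 1.0):
            raise ValueError("mu_w must be in [0, 1]")
        if self.tau1 <= 1.0 or self.tau2 <= 1.0:
            raise ValueError("power-law exponents must exceed 1")
        if self.min_comm > self.n:
            raise ValueError("min_comm exceeds n")
        if self.min_comm > self.max_comm:
            raise ValueError("min_comm > max_comm")
        if self.max_deg >= self.n:
            raise ValueError("max_deg must be below n")
        if self.avg_deg > self.max_deg:
            raise ValueError("avg_deg exceeds max_deg")
        # every node must fit its within-community degree in some community
        if (1.0 - self.mu_topo) * self.max_deg > self.max_comm - 1:
            raise ValueError("max_deg incompatible with max_comm at this mu_topo")


@dataclass
class BenchmarkNetwork:
    graph: WeightedGraph
    planted: np.ndarray
    spec: LFRSpec
    realized_mu_topo: float


def _powerlaw_ints(rng, exponent, lo, hi, size):
    """Discrete truncated power-law sample P(k) ~ k^-exponent on [lo, hi]."""
    ks = np.arange(lo, hi + 1, dtype=float)
    p = ks ** (-exponent)
    p /= p.sum()
    return rng.choice(np.arange(lo, hi + 1), size=size, p=p)


def _degree_sequence(rng, spec: LFRSpec) -> np.ndarray:
    # choose the lower cutoff so the truncated power-law mean ~= avg_deg
    best_lo, best_gap = 1, np.inf
    for lo in range(1, spec.max_deg + 1):
        ks = np.arange(lo, spec.max_deg + 1, dtype=float)
        p = ks ** (-spec.tau1)
        mean = (ks * p).sum() / p.sum()
        gap = abs(mean - spec.avg_deg)
        if gap < best_gap:
            best_lo, best_gap = lo, gap
    return _powerlaw_ints(rng, spec.tau1, best_lo, spec.max_deg, spec.n)


def _community_sizes(rng, spec: LFRSpec) -> np.ndarray:
    sizes: list = []
    while sum(sizes) < spec.n:
        sizes.append(int(_powerlaw_ints(rng, spec.tau2, spec.min_comm, spec.max_comm, 1)[0]))
    sizes[-1] -= sum(sizes) - spec.n
    if sizes[-1] < spec.min_comm:
        # grow the last community by shrinking the largest others
        while sizes[-1] < spec.min_comm:
            k = int(np.argmax(sizes[:-1]))
            if sizes[k] <= spec.min_comm:
                break
            sizes[k] -= 1
            sizes[-1] += 1
        if sizes[-1] < spec.min_comm:
            # fold the undersized remainder into the other communities
            rem = sizes.pop()
            k = 0
            while rem > 0:
                if not sizes:
                    raise ValueError("infeasible community-size spec")
                if sizes[k % len(sizes)] < spec.max_comm:
                    sizes[k % len(sizes)] += 1
                    rem -= 1
                k += 1
                if k > 100 * spec.n:
                    raise ValueError("infeasible community-size spec")
    return np.asarray(sizes, dtype=int)


def _pair_stubs(rng, stubs, forbidden, labels=None, cross_only=False, max_retry=100):
    """Uniformly pair stubs into simple edges with rejection."""
    edges = []
    stubs = list(stubs)
    rng.shuffle(stubs)
    retries = 0
    while len(stubs) >= 2:
        u = stubs.pop()
        placed = False
        for _ in range(min(max_retry, len(stubs))):
            k = int(rng.integers(len(stubs)))
            v = stubs[k]
            if v == u:
                continue
            key = (min(u, v), max(u, v))
            if key in forbidden:
                continue
            if cross_only and labels is not None and labels[u] == labels[v]:
                continue
            stubs.pop(k)
            forbidden.add(key)
            edges.append(key)
            placed = True
            break
        if not placed:
            retries += 1
            if retries > max_retry:
                break  # drop the leftover stubs
    return edges


def lfr_generate(spec: LFRSpec) -> BenchmarkNetwork:
    """Generate one weighted LFR-style benchmark network."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    deg = _degree_sequence(rng, spec)
    sizes = _community_sizes(rng, spec)
    n_comm = len(sizes)

    # split each node's degree into within/between stubs
    k_out = np.rint(spec.mu_topo * deg).astype(int)
    k_in = deg - k_out

    # assign nodes to communities: largest k_in first into a community
    # that can host it, chosen with probability proportional to capacity
    labels = np.full(spec.n, -1, dtype=np.int64)
    capacity = sizes.copy()
    order = np.argsort(-k_in, kind="stable")
    for i in order:
        feasible = np.flatnonzero((capacity > 0) & (sizes - 1 >= k_in[i]))
        if len(feasible) == 0:
            # no community can host this within-degree: shed stubs (shrink
            # the node's degree) rather than rewiring them across
            feasible = np.flatnonzero(capacity > 0)
            k_in[i] = min(k_in[i], sizes[feasible].max() - 1)
        # weighted random choice among feasible by remaining capacity
        p = capacity[feasible] / capacity[feasible].sum()
        c = int(rng.choice(feasible, p=p))
        labels[i] = c
        capacity[c] -= 1

    forbidden: set = set()
    within_edges = []
    for c in range(n_comm):
        members = np.flatnonzero(labels == c)
        stubs = np.repeat(members, k_in[members])
        if len(stubs) % 2 == 1:
            stubs = stubs[:-1]
        within_edges += _pair_stubs(rng, stubs, forbidden)

    stubs = np.repeat(np.arange(spec.n), k_out)
    if len(stubs) % 2 == 1:
        stubs = stubs[:-1]
    between_edges = _pair_stubs(rng, stubs, forbidden, labels=labels, cross_only=True)

    def beta_weights(mean, size):
        mean = min(max(mean, 0.01), 0.99)
        nu = spec.weight_concentration
        w = rng.beta(mean * nu, (1.0 - mean) * nu, size=size)
        return np.clip(w, 1e-6, 1.0)

    edges = within_edges + between_edges
    w = np.concatenate(
        [
            beta_weights(1.0 - spec.mu_w, len(within_edges)),
            beta_weights(spec.mu_w, len(between_edges)),
        ]
    ) if edges else np.zeros(0)
    src = np.asarray([e[0] for e in edges], dtype=np.int64)
    dst = np.asarray([e[1] for e in edges], dtype=np.int64)
    graph = WeightedGraph(node_ids=list(range(spec.n)), src=src, dst=dst, weights=w)
    graph.validate()
    cross = labels[src] != labels[dst]
    realized = float(cross.mean()) if len(edges) else 0.0
    return BenchmarkNetwork(graph=graph, planted=labels, spec=spec, realized_mu_topo=realized)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def nmi(p, q) -> float:
    """Normalized mutual information with arithmetic-mean normalization.

    Plug-in MI of the contingency table divided by the mean of the two
    label entropies; 0*ln(0) := 0.  Two identical single-cluster
    partitions have zero entropy and are, by convention, in perfect
    agreement: NMI = 1.
    """
    p = np.asarray(p)
    q = np.asarray(q)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("labelings must be 1-D and of equal length")
    n = len(p)
    _, pi = np.unique(p, return_inverse=True)
    _, qi = np.unique(q, return_inverse=True)
    table = np.zeros((pi.max() + 1, qi.max() + 1))
    np.add.at(table, (pi, qi), 1.0)
    pxy = table / n
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)

    def entropy(p):
        p = p[p > 0]
        return -float(np.sum(p * np.log(p)))

    # MI as H(x) + H(y) - H(x, y): exact 1.0 for identical partitions and
    # exactly symmetric in (p, q)
    hx, hy, hxy = entropy(px), entropy(py), entropy(pxy.ravel())
    mi = hx + hy - hxy
    denom = 0.5 * (hx + hy)
    if denom == 0.0:
        return 1.0  # both single-cluster
    return float(min(max(mi / denom, 0.0), 1.0))


def greedy_modularity(graph: WeightedGraph) -> np.ndarray:
    """Weighted greedy (CNM) modularity-maximization baseline labels."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(graph.n_nodes))
    for u, v, w in zip(graph.src, graph.dst, graph.weights):
        g.add_edge(int(u), int(v), weight=float(w))
    if g.number_of_edges() == 0:
        return np.zeros(graph.n_nodes, dtype=np.int64)
    comms = nx.algorithms.community.greedy_modularity_communities(g, weight="weight")
    labels = np.zeros(graph.n_nodes, dtype=np.int64)
    for c, members in enumerate(sorted((sorted(c) for c in comms))):
        labels[list(members)] = c
    return labels


def sbm_mcmc_method(graph: WeightedGraph, seed: int = 0, burnin: int = 75,
                    sweeps: int = 250) -> np.ndarray:
    """The package's SBM engine at benchmark-scale MCMC settings."""
    return mcmc_partition(graph, seed=seed, burnin=burnin, sweeps=sweeps).partition.labels


BUILTIN_METHODS = {
    "sbm_mcmc": sbm_mcmc_method,
    "greedy_modularity": lambda graph, seed=0: greedy_modularity(graph),
}


def default_benchmark_grid(n: int = 60) -> list:
    """Nine network types: mu_topo x mu_w x community-size skew."""
    specs = []
    for mu_topo, mu_w, (min_c, max_c, tau2) in [
        (0.05, 0.1, (10, 25, 1.5)),
        (0.05, 0.3, (10, 25, 1.5)),
        (0.05, 0.5, (8, 30, 2.5)),
        (0.2, 0.1, (10, 25, 1.5)),
        (0.2, 0.3, (8, 30, 2.5)),
        (0.2, 0.5, (10, 25, 1.5)),
        (0.4, 0.1, (8, 30, 2.5)),
        (0.4, 0.3, (10, 25, 1.5)),
        (0.4, 0.5, (8, 30, 2.5)),
    ]:
        specs.append(
            LFRSpec(
                n=n,
                mu_topo=mu_topo,
                mu_w=mu_w,
                min_comm=min_c,
                max_comm=max_c,
                tau2=tau2,
                max_deg=min(20, min_c * 2),
                name=f"mu{mu_topo}_w{mu_w}_c{min_c}-{max_c}",
            )
        )
    return specs


def run_benchmark(specs, methods=None, n_reps: int = 10, seed: int = 0) -> pd.DataFrame:
    """Mean/sd NMI per (network type, method) over seeded instances.

    ``methods`` maps a name to ``f(graph, seed) -> labels``; defaults to
    the SBM engine and the greedy-modularity baseline.  A method failure
    on an instance is recorded as NaN, never silently dropped.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if methods is None:
        methods = BUILTIN_METHODS
    rows = []
    for si, spec in enumerate(specs):
        spec_name = spec.name or f"spec{si}"
        scores: dict = {m: [] for m in methods}
        for rep in range(n_reps):
            inst_seed = derive_seed(seed, f"bench-{spec_name}-{rep}")
            net = lfr_generate(replace(spec, seed=inst_seed))
            for m, fn in methods.items():
                try:
                    labels = fn(net.graph, seed=derive_seed(inst_seed, m))
                    scores[m].append(nmi(labels, net.planted))
                except Exception:
                    scores[m].append(np.nan)
        for m in methods:
            arr = np.asarray(scores[m], dtype=float)
            rows.append(
                {
                    "network": spec_name,
                    "method": m,
                    "mean_nmi": float(np.nanmean(arr)) if np.isfinite(arr).any() else np.nan,
                    "sd_nmi": float(np.nanstd(arr, ddof=1)) if np.isfinite(arr).sum() > 1 else 0.0,
                    "n_ok": int(np.isfinite(arr).sum()),
                    "n_reps": n_reps,
                }
            )
    return pd.DataFrame(rows)


def planted_partition_graph(
    n: int = 60,
    n_blocks: int = 4,
    p_in: float = 0.9,
    p_out: float = 0.1,
    w_in: float = 0.8,
    w_out: float = 0.1,
    w_sd: float = 0.05,
    seed: int = 0,
) -> tuple:
    """Equal-block planted-partition weighted graph; returns (graph, labels).

    Edge presence is Bernoulli (``p_in`` within, ``p_out`` between);
    weights are Gaussian around ``w_in``/``w_out`` clipped to (0, 1].
    """
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(n_blocks), int(np.ceil(n / n_blocks)))[:n]
    iu, ju = np.triu_indices(n, k=1)
    same = labels[iu] == labels[ju]
    p = np.where(same, p_in, p_out)
    present = rng.random(len(iu)) < p
    mu = np.where(same, w_in, w_out)[present]
    w = np.clip(rng.normal(mu, w_sd), 1e-6, 1.0)
    graph = WeightedGraph(
        node_ids=list(range(n)),
        src=iu[present].astype(np.int64),
        dst=ju[present].astype(np.int64),
        weights=w,
    )
    return graph, labels
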