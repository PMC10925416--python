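"""Weighted-SBM community detection by description-length minimization.

An affinity factor, reshaped to a symmetric matrix, is a weighted graph
on neurons: edge weights in (0, 1] convey how likely two neurons are to
be interacting over the component's time window.  Communities are
inferred with a weighted stochastic block model: nodes are partitioned
into C groups, and for every group pair (r, s) the model has a Bernoulli
edge-placement density and an exponential edge-weight distribution.

Model selection is by minimum description length.  For a partition c,

    L(c) = -ln P(G | theta_hat, c) - ln P(theta_hat, c)

with, per block pair (all in nats):

* adjacency: microcanonical counting, ln C(N_rs, e_rs) over the N_rs
  dyads of the block pair (Stirling-equivalent to the Bernoulli
  likelihood at the MLE density e_rs / N_rs), plus one global uniform
  prior over how the total edge count distributes among block pairs;
* weights: exponential likelihood with rate integrated out under a
  Gamma(1, 1) conjugate prior, giving the closed-form marginal
  Gamma(1 + e_rs) / (1 + s_rs)^(1 + e_rs) for total weight s_rs, so
  weight parameters carry no plug-in cost;
* partition prior: uniform over the number of groups C, uniform over
  group-size compositions of n into C parts, uniform over labelings
  given the sizes.

The number of communities is thus inferred from the data: extra groups
must pay their prior cost in likelihood.  The posterior is explored by a
seeded Metropolis scheme over labelings with neighbor-biased single-node
moves and merge/split multi-flip moves, annealed (beta 1 -> beta_max)
and finished with a greedy beta -> infinity polish; the minimum-L state
visited is returned along with per-node label frequencies over the
post-burn-in samples (approximate model averaging).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from sklearn.base import BaseEstimator, ClusterMixin

from ._util import check_symmetric


# ---------------------------------------------------------------------------
# graph container
# ---------------------------------------------------------------------------

@dataclass
class WeightedGraph:
    """Simple undirected weighted graph; no self-loops, weights > 0."""

    node_ids: list
    src: np.ndarray
    dst: np.ndarray
    weights: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    def validate(self) -> None:
        if np.any(self.src == self.dst):
            raise ValueError("self-loops are not allowed")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be strictly positive")
        pairs = set(zip(np.minimum(self.src, self.dst), np.maximum(self.src, self.dst)))
        if len(pairs) != self.n_edges:
            raise ValueError("duplicate edges")

    def adjacency(self):
        """Per-node lists of (neighbor index array, weight array)."""
        nbr = [[] for _ in range(self.n_nodes)]
        wts = [[] for _ in range(self.n_nodes)]
        for u, v, w in zip(self.src, self.dst, self.weights):
            nbr[u].append(v)
            wts[u].append(w)
            nbr[v].append(u)
            wts[v].append(w)
        return (
            [np.asarray(x, dtype=np.int64) for x in nbr],
            [np.asarray(x, dtype=float) for x in wts],
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        for u, v, w in zip(self.src, self.dst, self.weights):
            g.add_edge(self.node_ids[u], self.node_ids[v], weight=float(w))
        return g

    @classmethod
    def from_networkx(cls, g) -> "WeightedGraph":
        node_ids = sorted(g.nodes())
        pos = {v: i for i, v in enumerate(node_ids)}
        src, dst, w = [], [], []
        for u, v, data in g.edges(data=True):
            src.append(pos[u])
            dst.append(pos[v])
            w.append(float(data.get("weight", 1.0)))
        return cls(node_ids, np.asarray(src, dtype=np.int64),
                   np.asarray(dst, dtype=np.int64), np.asarray(w))


def graph_from_matrix(A: np.ndarray, w_min: float = 0.0, node_ids=None) -> WeightedGraph:
    """Build a weighted graph from a symmetric non-negative matrix.

    Keeps every strictly positive entry >= ``w_min``; NaN entries
    (missing neurons) yield no edges; isolated nodes are retained.
    """
    A = np.asarray(A, dtype=float)
    check_symmetric(A, name="affinity matrix")
    n = A.shape[0]
    if node_ids is None:
        node_ids = list(range(n))
    iu, ju = np.triu_indices(n, k=1)
    vals = A[iu, ju]
    keep = np.isfinite(vals) & (vals > 0) & (vals >= w_min)
    return WeightedGraph(
        node_ids=list(node_ids),
        src=iu[keep].astype(np.int64),
        dst=ju[keep].astype(np.int64),
        weights=vals[keep],
    )


# ---------------------------------------------------------------------------
# description length
# ---------------------------------------------------------------------------

def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel to contiguous 0..C-1 by order of first occurrence."""
    labels = np.asarray(labels)
    seen: dict = {}
    out = np.empty(len(labels), dtype=np.int64)
    for k, lab in enumerate(labels):
        if lab not in seen:
            seen[lab] = len(seen)
        out[k] = seen[lab]
    return out


@dataclass
class Partition:
    """A node labeling with its description length."""

    labels: np.ndarray
    dl: float

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def groups(self) -> list:
        return [np.flatnonzero(self.labels == c) for c in range(self.n_communities)]


def _stats_from_labels(graph: WeightedGraph, labels: np.ndarray, C: int):
    n_r = np.bincount(labels, minlength=C).astype(float)
    E = np.zeros((C, C))
    S = np.zeros((C, C))
    if graph.n_edges:
        a = labels[graph.src]
        b = labels[graph.dst]
        np.add.at(E, (a, b), 1.0)
        np.add.at(E, (b, a), 1.0)
        np.add.at(S, (a, b), graph.weights)
        np.add.at(S, (b, a), graph.weights)
        idx = np.arange(C)
        E[idx, idx] /= 2.0
        S[idx, idx] /= 2.0
    return n_r, E, S


def _dl_from_stats(n_r: np.ndarray, E: np.ndarray, S: np.ndarray, n_total: int) -> float:
    C = len(n_r)
    N = np.outer(n_r, n_r)
    np.fill_diagonal(N, n_r * (n_r - 1) / 2.0)
    iu = np.triu_indices(C)
    Nv, ev, sv = N[iu], E[iu], S[iu]
    # microcanonical adjacency: ln C(N_rs, e_rs) possible placements per
    # block pair, plus one global uniform prior over how the E edges
    # distribute among the C(C+1)/2 block pairs (multiset coefficient)
    adj = np.sum(gammaln(Nv + 1.0) - gammaln(ev + 1.0) - gammaln(Nv - ev + 1.0))
    B = C * (C + 1) / 2.0
    E_tot = ev.sum()
    e_prior = gammaln(B + E_tot) - gammaln(E_tot + 1.0) - gammaln(B)
    wt = np.sum(-gammaln(1.0 + ev) + (1.0 + ev) * np.log1p(sv))
    n = n_total
    part = (
        np.log(n)
        + (gammaln(n) - gammaln(C) - gammaln(n - C + 1))
        + (gammaln(n + 1) - np.sum(gammaln(n_r + 1)))
    )
    return float(adj + e_prior + wt + part)


def description_length(graph: WeightedGraph, labels) -> float:
    """Description length L of a labeling; deterministic, label-permutation
    invariant, finite for any labeling that covers all nodes."""
    labels = canonical_labels(np.asarray(labels))
    if len(labels) != graph.n_nodes:
        raise ValueError("labels must cover every node")
    C = int(labels.max()) + 1 if len(labels) else 0
    n_r, E, S = _stats_from_labels(graph, labels, C)
    return _dl_from_stats(n_r, E, S, graph.n_nodes)


# ---------------------------------------------------------------------------
# MCMC over partitions
# ---------------------------------------------------------------------------

class _SBMState:
    """Partition + block-pair sufficient statistics with incremental updates.

    Statistics are (n_r, E, S): group sizes, edge counts and weight sums
    per block pair (symmetric storage; diagonal counts each within-group
    edge once).  Every proposal builds candidate statistics, evaluates
    the description length from them, and commits only on acceptance, so
    incremental bookkeeping and from-scratch recomputation coincide by
    construction; ``assert_consistent`` verifies it.
    """

    def __init__(self, graph: WeightedGraph, labels: np.ndarray):
        self.graph = graph
        self.n = graph.n_nodes
        self.labels = canonical_labels(labels)
        self.nbr, self.wts = graph.adjacency()
        self.C = int(self.labels.max()) + 1 if self.n else 0
        self.n_r, self.E, self.S = _stats_from_labels(graph, self.labels, self.C)
        self.dl = _dl_from_stats(self.n_r, self.E, self.S, self.n)

    # -- candidate construction -------------------------------------------
    def _node_move_candidate(self, i: int, b: int):
        """Stats if node i moves to block b (b == C opens a new block)."""
        a = self.labels[i]
        C = self.C
        new_block = b == C
        Cc = C + 1 if new_block else C
        n_r = np.zeros(Cc)
        n_r[:C] = self.n_r
        E = np.zeros((Cc, Cc))
        S = np.zeros((Cc, Cc))
        E[:C, :C] = self.E
        S[:C, :C] = self.S
        t = self.labels[self.nbr[i]]
        w = self.wts[i]
        # aggregated edge counts / weight sums from node i into each block;
        # row+col updates double-hit the diagonal, corrected explicitly
        cnt = np.bincount(t, minlength=Cc).astype(float)
        wsum = np.bincount(t, weights=w, minlength=Cc) if len(t) else np.zeros(Cc)
        E[a, :] -= cnt
        E[:, a] -= cnt
        E[a, a] += cnt[a]
        S[a, :] -= wsum
        S[:, a] -= wsum
        S[a, a] += wsum[a]
        E[b, :] += cnt
        E[:, b] += cnt
        E[b, b] -= cnt[b]
        S[b, :] += wsum
        S[:, b] += wsum
        S[b, b] -= wsum[b]
        n_r[a] -= 1
        n_r[b] += 1
        closed = n_r[a] == 0
        if closed:
            keep = np.arange(Cc) != a
            n_r = n_r[keep]
            E = E[np.ix_(keep, keep)]
            S = S[np.ix_(keep, keep)]
        return n_r, E, S, closed

    def propose_node_move(self, i: int, b: int):
        n_r, E, S, closed = self._node_move_candidate(i, b)
        dl = _dl_from_stats(n_r, E, S, self.n)
        return dl, (i, b, n_r, E, S, closed)

    def commit_node_move(self, payload, dl: float) -> None:
        i, b, n_r, E, S, closed = payload
        a = self.labels[i]
        self.labels[i] = b
        if closed:
            self.labels[self.labels > a] -= 1
            self.C = self.C - 1 + (1 if b == self.C else 0)
        elif b == self.C:
            self.C += 1
        self.n_r, self.E, self.S = n_r, E, S
        self.dl = dl

    def propose_merge(self, a: int, b: int):
        """Stats if blocks a and b merge (b folded into a, b removed)."""
        keep = np.arange(self.C) != b
        n_r = self.n_r.copy()
        E = self.E.copy()
        S = self.S.copy()
        E[a, :] += E[b, :]
        E[:, a] += E[:, b]
        E[a, a] -= self.E[a, b]  # row+col add counted the (a,b) cell twice,
        S[a, :] += S[b, :]       # and within-b edges land on the diagonal once
        S[:, a] += S[:, b]
        S[a, a] -= self.S[a, b]
        n_r[a] += n_r[b]
        n_r = n_r[keep]
        E = E[np.ix_(keep, keep)]
        S = S[np.ix_(keep, keep)]
        dl = _dl_from_stats(n_r, E, S, self.n)
        return dl, (a, b, n_r, E, S)

    def commit_merge(self, payload, dl: float) -> None:
        a, b, n_r, E, S = payload
        self.labels[self.labels == b] = a
        self.labels[self.labels > b] -= 1
        self.C -= 1
        self.n_r, self.E, self.S = n_r, E, S
        self.dl = dl

    def propose_split(self, labels_new: np.ndarray):
        """Arbitrary relabeling (used for splits): stats from scratch."""
        labels_new = canonical_labels(labels_new)
        C = int(labels_new.max()) + 1
        n_r, E, S = _stats_from_labels(self.graph, labels_new, C)
        dl = _dl_from_stats(n_r, E, S, self.n)
        return dl, (labels_new, C, n_r, E, S)

    def commit_relabel(self, payload, dl: float) -> None:
        labels_new, C, n_r, E, S = payload
        self.labels = labels_new
        self.C = C
        self.n_r, self.E, self.S = n_r, E, S
        self.dl = dl

    def assert_consistent(self, tol: float = 1e-9) -> None:
        n_r, E, S = _stats_from_labels(self.graph, self.labels, self.C)
        if not (
            np.allclose(n_r, self.n_r)
            and np.allclose(E, self.E)
            and np.allclose(S, self.S, atol=1e-9)
        ):
            raise AssertionError("incremental block statistics drifted")
        dl = _dl_from_stats(n_r, E, S, self.n)
        if abs(dl - self.dl) > tol:
            raise AssertionError(
                f"incremental dl {self.dl} != recomputed {dl}"
            )


@dataclass
class MCMCResult:
    partition: Partition
    marginals: np.ndarray  # n x C_max per-node label frequencies (rows sum to 1)
    n_samples: int
    acceptance_rate: float
    dl_trace: np.ndarray = field(default=None, repr=False)


def _greedy_polish(state: _SBMState, max_passes: int = 50) -> None:
    """Deterministic beta -> infinity phase: best single-node moves and
    block merges until no strict improvement remains."""
    for _ in range(max_passes):
        improved = False
        for i in range(state.n):
            a = state.labels[i]
            best_dl, best_payload = state.dl, None
            candidates = list(range(state.C))
            if state.n_r[a] > 1:
                candidates.append(state.C)  # open a new block
            for b in candidates:
                if b == a:
                    continue
                dl, payload = state.propose_node_move(i, b)
                if dl < best_dl - 1e-12:
                    best_dl, best_payload = dl, payload
            if best_payload is not None:
                state.commit_node_move(best_payload, best_dl)
                improved = True
        # merges
        while state.C >= 2:
            best_dl, best_payload = state.dl, None
            for a in range(state.C):
                for b in range(a + 1, state.C):
                    dl, payload = state.propose_merge(a, b)
                    if dl < best_dl - 1e-12:
                        best_dl, best_payload = dl, payload
            if best_payload is None:
                break
            state.commit_merge(best_payload, best_dl)
            improved = True
        if not improved:
            break


def mcmc_partition(
    graph: WeightedGraph,
    seed: int = 0,
    burnin: int = 200,
    sweeps: int = 800,
    beta_max: float = 5.0,
    multiflip_prob: float = 0.1,
    init_labels=None,
    validate: bool = False,
) -> MCMCResult:
    """Sample partitions and return the minimum-description-length state.

    The chain starts from singletons, runs ``burnin + sweeps`` sweeps of
    n proposals each under a geometric inverse-temperature ramp
    1 -> ``beta_max``, then applies a deterministic greedy polish to the
    best state visited.  Label samples from the post-burn-in phase give
    per-node marginal label frequencies.  Fully seeded; ``validate``
    checks incremental bookkeeping against from-scratch recomputation
    after every accepted move.
    """
    n = graph.n_nodes
    if n == 0:
        raise ValueError("graph has no nodes")
    rng = np.random.default_rng(seed)
    if init_labels is None:
        init_labels = np.arange(n)
    state = _SBMState(graph, np.asarray(init_labels))

    best_labels = state.labels.copy()
    best_dl = state.dl
    samples = []
    total = burnin + sweeps
    n_prop = 0
    n_acc = 0
    dl_trace = np.empty(total)

    for sweep in range(total):
        beta = beta_max ** (sweep / max(total - 1, 1))
        for _ in range(n):
            n_prop += 1
            if state.C >= 2 and rng.random() < multiflip_prob:
                # multi-flip: merge two blocks or split one
                if rng.random() < 0.5:
                    a, b = rng.choice(state.C, size=2, replace=False)
                    dl, payload = state.propose_merge(min(a, b), max(a, b))
                    accept = dl < state.dl or rng.random() < np.exp(
                        -beta * (dl - state.dl)
                    )
                    if accept:
                        state.commit_merge(payload, dl)
                        n_acc += 1
                        if validate:
                            state.assert_consistent()
                else:
                    big = np.flatnonzero(state.n_r >= 2)
                    if len(big) == 0:
                        continue
                    a = int(rng.choice(big))
                    members = np.flatnonzero(state.labels == a)
                    assign = rng.integers(0, 2, size=len(members))
                    if assign.min() == assign.max():
                        assign[0] = 1 - assign[0]
                    labels_new = state.labels.copy()
                    labels_new[members[assign == 1]] = state.C
                    dl, payload = state.propose_split(labels_new)
                    accept = dl < state.dl or rng.random() < np.exp(
                        -beta * (dl - state.dl)
                    )
                    if accept:
                        state.commit_relabel(payload, dl)
                        n_acc += 1
                        if validate:
                            state.assert_consistent()
            else:
                i = int(rng.integers(n))
                a = state.labels[i]
                if len(state.nbr[i]) and rng.random() < 0.8:
                    j = int(rng.choice(state.nbr[i]))
                    b = int(state.labels[j])
                else:
                    b = int(rng.integers(state.C + 1))
                if b == a or (b == state.C and state.n_r[a] == 1):
                    continue
                dl, payload = state.propose_node_move(i, b)
                accept = dl < state.dl or rng.random() < np.exp(
                    -beta * (dl - state.dl)
                )
                if accept:
                    state.commit_node_move(payload, dl)
                    n_acc += 1
                    if validate:
                        state.assert_consistent()
            if state.dl < best_dl - 1e-12:
                best_dl = state.dl
                best_labels = state.labels.copy()
        dl_trace[sweep] = state.dl
        if sweep >= burnin:
            samples.append(canonical_labels(state.labels))

    # greedy beta->infinity phase from several starts: the best state
    # visited, the final chain state, fresh singletons (agglomerative
    # descent), the connected components, and a single block.  The last
    # three escape description-length valleys in which neither pairwise
    # merges from singletons nor single-node exits from one block improve
    # (e.g. a small clique among isolated nodes).
    for start in (
        best_labels,
        state.labels.copy(),
        np.arange(n),
        _component_labels(graph),
        np.zeros(n, dtype=np.int64),
    ):
        polish = _SBMState(graph, start)
        _greedy_polish(polish)
        if validate:
            polish.assert_consistent()
        if polish.dl < best_dl:
            best_dl, best_labels = polish.dl, polish.labels.copy()

    best_labels = canonical_labels(best_labels)
    best_dl = description_length(graph, best_labels)

    if samples:
        c_max = max(int(s.max()) + 1 for s in samples)
        marg = np.zeros((n, c_max))
        for s in samples:
            marg[np.arange(n), s] += 1.0
        marg /= len(samples)
    else:
        marg = np.zeros((n, best_labels.max() + 1))
        marg[np.arange(n), best_labels] = 1.0

    return MCMCResult(
        partition=Partition(labels=best_labels, dl=best_dl),
        marginals=marg,
        n_samples=len(samples),
        acceptance_rate=n_acc / max(n_prop, 1),
        dl_trace=dl_trace,
    )


def _component_labels(graph: WeightedGraph) -> np.ndarray:
    """Connected-component labels (union-find)."""
    parent = np.arange(graph.n_nodes)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in zip(graph.src, graph.dst):
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    return canonical_labels(np.array([find(i) for i in range(graph.n_nodes)]))


def _set_partitions(n: int):
    """All partitions of range(n) as restricted-growth label vectors."""
    labels = np.zeros(n, dtype=np.int64)
    maxes = np.zeros(n, dtype=np.int64)

    def rec(k):
        if k == n:
            yield labels.copy()
            return
        top = maxes[k - 1] if k else -1
        for c in range(top + 2):
            labels[k] = c
            maxes[k] = max(top, c)
            yield from rec(k + 1)

    yield from rec(0)


def exhaustive_minimum(graph: WeightedGraph) -> Partition:
    """Global minimum-description-length partition by enumeration (n <= 12).

    Ties resolve to the lexicographically smallest canonical labeling
    (the enumeration order).
    """
    n = graph.n_nodes
    if n > 12:
        raise ValueError("exhaustive search is limited to n <= 12")
    best, best_dl = None, np.inf
    for labels in _set_partitions(n):
        dl = description_length(graph, labels)
        if dl < best_dl - 1e-12:
            best_dl, best = dl, labels
    return Partition(labels=best, dl=best_dl)


def block_graph(graph: WeightedGraph, partition: Partition) -> WeightedGraph:
    """Coarse-grained graph: one node per community, edges weighted by the
    mean weight of the edges between (or within, dropped as self-loops)
    the two communities."""
    C = partition.n_communities
    labels = partition.labels
    wsum = np.zeros((C, C))
    cnt = np.zeros((C, C))
    a, b = labels[graph.src], labels[graph.dst]
    np.add.at(wsum, (a, b), graph.weights)
    np.add.at(wsum, (b, a), graph.weights)
    np.add.at(cnt, (a, b), 1.0)
    np.add.at(cnt, (b, a), 1.0)
    iu, ju = np.triu_indices(C, k=1)
    keep = cnt[iu, ju] > 0
    return WeightedGraph(
        node_ids=[f"block{c}" for c in range(C)],
        src=iu[keep].astype(np.int64),
        dst=ju[keep].astype(np.int64),
        weights=wsum[iu, ju][keep] / cnt[iu, ju][keep],
    )


def refine_partition(
    graph: WeightedGraph, partition: Partition, seed: int = 0, **mcmc_kwargs
) -> Partition:
    """Optional one-level refinement: re-run community detection on the
    block graph, yielding communities-of-communities mapped back to the
    original nodes (a coarse view of hierarchical structure, not a full
    nested model)."""
    if partition.n_communities <= 1:
        return Partition(labels=np.zeros(graph.n_nodes, dtype=np.int64),
                         dl=partition.dl)
    bg = block_graph(graph, partition)
    res = mcmc_partition(bg, seed=seed, **mcmc_kwargs)
    super_labels = res.partition.labels[partition.labels]
    return Partition(labels=canonical_labels(super_labels),
                     dl=description_length(graph, super_labels))


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def community_report(
    graph: WeightedGraph,
    partition: Partition,
    model=None,
    component: int | None = None,
    traces=None,
    temporal_threshold: float = 0.5,
    top_animals: int = 3,
) -> dict:
    """Per-community membership and weight summary, optionally with the
    trace evidence behind one tensor component.

    For a chosen component, the active window is where the temporal
    factor exceeds ``temporal_threshold`` times its maximum, and trace
    snippets of community members are extracted for the top-loading
    animals -- the "revert to the original traces" sanity view.
    """
    labels = partition.labels
    report: dict = {"n_communities": partition.n_communities, "dl": partition.dl,
                    "communities": []}
    W = np.zeros((graph.n_nodes, graph.n_nodes))
    W[graph.src, graph.dst] = graph.weights
    W = W + W.T
    for c in range(partition.n_communities):
        members = np.flatnonzero(labels == c)
        inside = W[np.ix_(members, members)]
        outside = W[np.ix_(members, np.flatnonzero(labels != c))]
        iu = np.triu_indices(len(members), k=1)
        intra = float(inside[iu].mean()) if len(members) > 1 else 0.0
        inter = float(outside.mean()) if outside.size else 0.0
        report["communities"].append(
            {
                "label": int(c),
                "members": [graph.node_ids[m] for m in members],
                "size": int(len(members)),
                "intra_weight_mean": intra,
                "inter_weight_mean": inter,
            }
        )
    if model is not None and component is not None:
        f_t = model.temporal[:, component]
        f_w = model.animal[:, component]
        window = np.flatnonzero(f_t >= temporal_threshold * f_t.max())
        top = np.argsort(-f_w, kind="stable")[:top_animals]
        report["component"] = {
            "index": int(component),
            "lambda": float(model.lambdas[component]),
            "active_window": [int(window.min()), int(window.max()) + 1]
            if len(window)
            else None,
            "top_animals": [int(w) for w in top],
        }
        if traces is not None:
            pos = {nid: k for k, nid in enumerate(traces.neuron_ids)}
            snippets = {}
            for comm in report["communities"]:
                for nid in comm["members"]:
                    if nid not in pos:
                        raise ValueError(f"unknown neuron ID {nid!r}")
            if len(window):
                lo, hi = int(window.min()), int(window.max()) + 1
                for w in top:
                    snippets[int(w)] = {
                        nid: traces.activity[w, pos[nid], lo:hi].copy()
                        for comm in report["communities"]
                        for nid in comm["members"]
                    }
            report["component"]["trace_snippets"] = snippets
    return report


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class WeightedSBM(BaseEstimator, ClusterMixin):
    """Weighted-SBM community detection (description-length MCMC).

    Accepts either a symmetric affinity/adjacency matrix or a
    :class:`WeightedGraph` in :meth:`fit`.

    Parameters
    ----------
    w_min : float, default 0.0
        Matrix entries below this are not turned into edges.
    burnin, sweeps : MCMC schedule (sweeps of n proposals each).
    beta_max : float, default 5.0
        Final inverse temperature of the geometric annealing ramp.
    random_state : int, default 0

    Attributes (after fit)
    ----------
    labels_ : canonical community labels per node
    description_length_ : L of the best partition found
    n_communities_ : inferred number of groups
    marginals_ : per-node label frequencies over post-burn-in samples
    """

    def __init__(self, w_min=0.0, burnin=200, sweeps=800, beta_max=5.0,
                 multiflip_prob=0.1, random_state=0):
        self.w_min = w_min
        self.burnin = burnin
        self.sweeps = sweeps
        self.beta_max = beta_max
        self.multiflip_prob = multiflip_prob
        self.random_state = random_state

    def fit(self, X, y=None):
        graph = X if isinstance(X, WeightedGraph) else graph_from_matrix(X, self.w_min)
        res = mcmc_partition(
            graph,
            seed=self.random_state,
            burnin=self.burnin,
            sweeps=self.sweeps,
            beta_max=self.beta_max,
            multiflip_prob=self.multiflip_prob,
        )
        self.graph_ = graph
        self.result_ = res
        self.labels_ = res.partition.labels
        self.description_length_ = res.partition.dl
        self.n_communities_ = res.partition.n_communities
        self.marginals_ = res.marginals
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
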