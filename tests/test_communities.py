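"""Weighted-SBM description length, MCMC partition inference, reporting."""

import numpy as np
import pytest
from scipy.special import gammaln

import dynconn as dc
from dynconn.communities import _SBMState, _greedy_polish, canonical_labels

from conftest import random_weighted_graph


def dl_oracle(graph, labels):
    """Straight-from-the-formula description length, independent of the
    package's vectorized implementation."""
    labels = canonical_labels(np.asarray(labels))
    C = labels.max() + 1
    n = graph.n_nodes
    # block-pair sufficient statistics by explicit loops
    e = np.zeros((C, C))
    s = np.zeros((C, C))
    for u, v, w in zip(graph.src, graph.dst, graph.weights):
        a, b = sorted((labels[u], labels[v]))
        e[a, b] += 1
        s[a, b] += w
    n_r = np.array([(labels == r).sum() for r in range(C)], dtype=float)
    total = 0.0
    E_tot = 0.0
    for r in range(C):
        for t in range(r, C):
            N = n_r[r] * (n_r[r] - 1) / 2 if r == t else n_r[r] * n_r[t]
            total += gammaln(N + 1) - gammaln(e[r, t] + 1) - gammaln(N - e[r, t] + 1)
            total += -gammaln(1 + e[r, t]) + (1 + e[r, t]) * np.log1p(s[r, t])
            E_tot += e[r, t]
    B = C * (C + 1) / 2
    total += gammaln(B + E_tot) - gammaln(E_tot + 1) - gammaln(B)
    total += np.log(n) + gammaln(n) - gammaln(C) - gammaln(n - C + 1)
    total += gammaln(n + 1) - sum(gammaln(n_r + 1))
    return float(total)


class TestGraphFromMatrix:
    def test_all_positive_gives_complete_graph(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(0.1, 1.0, (5, 5))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        g = dc.graph_from_matrix(A, w_min=0.0)
        assert g.n_edges == 10

    def test_threshold_above_max_empty(self):
        A = np.array([[0, 0.3], [0.3, 0]])
        g = dc.graph_from_matrix(A, w_min=0.5)
        assert g.n_edges == 0 and g.n_nodes == 2

    def test_block_matrix_edge_count(self):
        A = np.full((6, 6), 0.05)
        A[:3, :3] = 0.9
        A[3:, 3:] = 0.9
        np.fill_diagonal(A, 0)
        g = dc.graph_from_matrix(A, w_min=0.1)
        assert g.n_edges == 6
        assert set(zip(g.src.tolist(), g.dst.tolist())) == {
            (0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)
        }

    def test_asymmetric_rejected(self):
        A = np.zeros((3, 3))
        A[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            dc.graph_from_matrix(A)


class TestDescriptionLength:
    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(2)
        g = random_weighted_graph(7, 0.6, rng)
        labels = np.array([0, 1, 0, 2, 1, 2, 0])
        perm = np.array([2, 0, 2, 1, 0, 1, 2])  # same partition, relabeled
        assert dc.description_length(g, labels) == dc.description_length(g, perm)

    def test_two_cliques_prefer_planted_split(self, two_cliques_graph):
        two = dc.description_length(two_cliques_graph, [0] * 4 + [1] * 4)
        one = dc.description_length(two_cliques_graph, [0] * 8)
        assert two < one

    def test_matches_formula_oracle_on_all_partitions(self):
        """Exhaustive enumeration on 6 nodes: the package's dl equals an
        independent straight-from-formula oracle for all 203 partitions."""
        rng = np.random.default_rng(4)
        g = random_weighted_graph(6, 0.5, rng)
        from dynconn.communities import _set_partitions

        count = 0
        for labels in _set_partitions(6):
            assert dc.description_length(g, labels) == pytest.approx(
                dl_oracle(g, labels), abs=1e-9
            )
            count += 1
        assert count == 203  # Bell number B(6)

    def test_empty_graph_prior_only(self):
        g = dc.WeightedGraph(list(range(4)), np.array([], int), np.array([], int),
                             np.array([]))
        dl = dc.description_length(g, [0, 0, 1, 1])
        assert np.isfinite(dl) and dl == pytest.approx(dl_oracle(g, [0, 0, 1, 1]), abs=1e-12)


class TestMCMC:
    def test_two_cliques_recovered_every_seed(self, two_cliques_graph):
        for seed in range(10):
            res = dc.mcmc_partition(two_cliques_graph, seed=seed, burnin=50, sweeps=150)
            assert dc.nmi(res.partition.labels, [0] * 4 + [1] * 4) == 1.0

    def test_matches_exhaustive_optimum_on_small_graphs(self):
        """Best MCMC state never beats and almost always equals the
        enumerated global minimum-dl partition."""
        rng = np.random.default_rng(7)
        match = 0
        n_graphs = 10
        for k in range(n_graphs):
            g = random_weighted_graph(int(rng.integers(6, 9)), 0.5, rng)
            ex = dc.exhaustive_minimum(g)
            res = dc.mcmc_partition(g, seed=100 + k, burnin=200, sweeps=800)
            assert res.partition.dl >= ex.dl - 1e-9
            match += abs(res.partition.dl - ex.dl) <= 1e-9
        assert match >= n_graphs - 1

    def test_seeded_determinism(self, two_cliques_graph):
        r1 = dc.mcmc_partition(two_cliques_graph, seed=3, burnin=30, sweeps=60)
        r2 = dc.mcmc_partition(two_cliques_graph, seed=3, burnin=30, sweeps=60)
        np.testing.assert_array_equal(r1.partition.labels, r2.partition.labels)
        assert r1.partition.dl == r2.partition.dl
        np.testing.assert_array_equal(r1.marginals, r2.marginals)

    def test_incremental_bookkeeping_matches_recomputation(self):
        """validate=True asserts stats and dl after every accepted move."""
        rng = np.random.default_rng(11)
        g = random_weighted_graph(10, 0.5, rng)
        dc.mcmc_partition(g, seed=5, burnin=20, sweeps=50, validate=True)

    def test_marginals_rows_sum_to_one(self):
        rng = np.random.default_rng(13)
        g = random_weighted_graph(9, 0.6, rng)
        res = dc.mcmc_partition(g, seed=2, burnin=20, sweeps=60)
        np.testing.assert_allclose(res.marginals.sum(axis=1), 1.0, atol=1e-12)

    def test_planted_partition_recovery(self):
        g, lab = dc.planted_partition_graph(n=60, n_blocks=4, seed=1)
        res = dc.mcmc_partition(g, seed=1, burnin=100, sweeps=300)
        assert dc.nmi(res.partition.labels, lab) >= 0.95

    def test_weight_shuffled_null_not_more_communities(self):
        """Shuffling weights on the same topology must not increase the
        inferred number of communities (no spurious aggregation)."""
        wins = 0
        for s in range(10):
            g, _ = dc.planted_partition_graph(n=40, n_blocks=3, seed=200 + s)
            rs = np.random.default_rng(s)
            gnull = dc.WeightedGraph(g.node_ids, g.src, g.dst, rs.permutation(g.weights))
            Cs = dc.mcmc_partition(g, seed=s, burnin=60, sweeps=200).partition.n_communities
            Cn = dc.mcmc_partition(gnull, seed=s, burnin=60, sweeps=200).partition.n_communities
            wins += Cn <= Cs
        assert wins >= 8

    def test_greedy_polish_state_consistency(self):
        rng = np.random.default_rng(17)
        g = random_weighted_graph(12, 0.4, rng)
        st = _SBMState(g, np.arange(12))
        _greedy_polish(st)
        st.assert_consistent()


class TestRefinement:
    def test_block_graph_mean_weights(self, two_cliques_graph):
        g = two_cliques_graph
        # add a weak bridge so the block graph has one edge
        g2 = dc.WeightedGraph(g.node_ids, np.r_[g.src, 0], np.r_[g.dst, 4],
                              np.r_[g.weights, 0.2])
        part = dc.Partition(labels=np.array([0] * 4 + [1] * 4), dl=0.0)
        bg = dc.block_graph(g2, part)
        assert bg.n_nodes == 2 and bg.n_edges == 1
        assert bg.weights[0] == pytest.approx(0.2)

    def test_refinement_is_a_coarsening(self):
        """Super-labels are constant within each base community and never
        more numerous than the base communities."""
        rng = np.random.default_rng(21)
        g = random_weighted_graph(20, 0.4, rng)
        base = dc.mcmc_partition(g, seed=0, burnin=30, sweeps=80).partition
        refined = dc.refine_partition(g, base, seed=1, burnin=20, sweeps=60)
        assert refined.n_communities <= base.n_communities
        for c in range(base.n_communities):
            members = np.flatnonzero(base.labels == c)
            assert len(set(refined.labels[members])) == 1
        assert np.isfinite(refined.dl)


class TestCommunityReport:
    def test_planted_report_contents(self, two_circuit_spec):
        traces, truth = dc.simulate_traces(two_circuit_spec)
        series = dc.DifferentialAffinity().fit_transform(traces)
        tensor = dc.build_tensor(series)
        cp = dc.NonnegativeCP(rank=2, n_restarts=4, random_state=0).fit(tensor)
        A = dc.factor_to_matrix(cp.factors_[2][:, 0], tensor.pair_map)
        g = dc.graph_from_matrix(A, node_ids=tensor.neuron_ids)
        res = dc.mcmc_partition(g, seed=0, burnin=50, sweeps=150)
        rep = dc.community_report(g, res.partition, model=cp.model_, component=0,
                                  traces=traces)
        sizes = sum(c["size"] for c in rep["communities"])
        assert sizes == traces.n_neurons
        # at least one community is weight-coherent (the planted circuit)
        assert any(
            c["size"] > 1 and c["intra_weight_mean"] >= c["inter_weight_mean"]
            for c in rep["communities"]
        )
        lo, hi = rep["component"]["active_window"]
        f_t = cp.model_.temporal[:, 0]
        assert lo <= int(np.argmax(f_t)) < hi
        assert set(rep["component"]["trace_snippets"]) == set(
            rep["component"]["top_animals"]
        )

    def test_one_hot_temporal_factor_window(self, two_cliques_graph):
        f = np.zeros((50, 1))
        f[17, 0] = 1.0
        model = dc.CPModel(rank=1, factors=(f, np.ones((2, 1)), np.ones((28, 1))),
                           lambdas=np.ones(1), objective=0.0,
                           objective_history=np.zeros(1), n_iter=1, converged=True)
        part = dc.Partition(labels=np.zeros(8, dtype=int), dl=0.0)
        rep = dc.community_report(two_cliques_graph, part, model=model, component=0)
        lo, hi = rep["component"]["active_window"]
        assert lo <= 17 < hi

    def test_unknown_neuron_id_rejected(self, two_cliques_graph, single_circuit_spec):
        traces, _ = dc.simulate_traces(single_circuit_spec)
        f = np.ones((traces.n_timepoints, 1))
        model = dc.CPModel(rank=1, factors=(f, np.ones((2, 1)), np.ones((28, 1))),
                           lambdas=np.ones(1), objective=0.0,
                           objective_history=np.zeros(1), n_iter=1, converged=True)
        part = dc.Partition(labels=np.zeros(8, dtype=int), dl=0.0)
        with pytest.raises(ValueError, match="unknown neuron"):
            dc.community_report(two_cliques_graph, part, model=model, component=0,
                                traces=traces)
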