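"""Fixed-partition Q, PC, WD against independent oracles; hub identification."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

import lesionconn as lc
from lesionconn.containers import BinaryGraph
from lesionconn.errors import (
    DegenerateInputError,
    ParameterError,
    UndefinedMetricError,
)

from conftest import random_connectome


# --------------------------------------------------------------------------
# brute-force oracles (pure-python edge enumeration, no reuse of the
# implementation's linear algebra)


def oracle_q(adj, labels):
    edges = [(i, j) for i, j in zip(*np.where(np.triu(adj, 1)))]
    L = len(edges)
    q = 0.0
    for m in set(labels):
        l_s = sum(1 for i, j in edges if labels[i] == m and labels[j] == m)
        d_s = sum(int(adj[i].sum()) for i in range(len(labels)) if labels[i] == m)
        q += l_s / L - (d_s / (2 * L)) ** 2
    return q


def oracle_pc(adj, labels):
    n = len(labels)
    pc = np.zeros(n)
    for i in range(n):
        k = int(adj[i].sum())
        if k == 0:
            continue
        acc = 0.0
        for m in set(labels):
            kis = sum(1 for j in range(n) if adj[i, j] and labels[j] == m)
            acc += (kis / k) ** 2
        pc[i] = 1.0 - acc
    return pc


def oracle_wd(adj, labels):
    n = len(labels)
    kappa = np.array(
        [sum(1 for j in range(n) if adj[i, j] and labels[j] == labels[i]) for i in range(n)]
    )
    wd = np.zeros(n)
    for m in set(labels):
        idx = [i for i in range(n) if labels[i] == m]
        mu = np.mean(kappa[idx])
        sigma = np.sqrt(np.mean((kappa[idx] - mu) ** 2))
        if sigma > 0:
            for i in idx:
                wd[i] = (kappa[i] - mu) / sigma
    return wd


def make_graph(adj, nodes=None):
    return BinaryGraph(adjacency=adj, nodes=nodes if nodes is not None else
                       np.arange(adj.shape[0]), threshold_p=1.0)


def random_graph_and_partition(rng, n):
    adj = rng.random((n, n)) < rng.uniform(0.15, 0.6)
    adj = np.triu(adj, 1)
    adj = adj | adj.T
    labels = rng.integers(1, rng.integers(2, 6), size=n)
    labels[: labels.max()] = np.arange(1, labels.max() + 1)  # every label occurs
    return adj, labels


def test_metrics_match_bruteforce_oracles(rng):
    """Q, PC, WD agree with edge-enumeration oracles on random graphs."""
    checked = 0
    while checked < 60:
        n = int(rng.integers(5, 31))
        adj, labels = random_graph_and_partition(rng, n)
        if not np.triu(adj, 1).any():
            continue
        g = make_graph(adj)
        part = lc.Partition.from_labels(labels)
        assert lc.modularity_q(g, part) == pytest.approx(oracle_q(adj, labels), abs=1e-12)
        np.testing.assert_allclose(
            lc.participation_coefficients(g, part), oracle_pc(adj, labels), atol=1e-12
        )
        np.testing.assert_allclose(
            lc.within_module_degree_z(g, part), oracle_wd(adj, labels), atol=1e-12
        )
        checked += 1


def test_modularity_matches_networkx(rng):
    """Cross-check Q against networkx's community.modularity."""
    for _ in range(30):
        n = int(rng.integers(6, 25))
        adj, labels = random_graph_and_partition(rng, n)
        if not np.triu(adj, 1).any():
            continue
        G = nx.from_numpy_array(adj.astype(int))
        comms = [{i for i in range(n) if labels[i] == m} for m in sorted(set(labels))]
        expect = nx.community.modularity(G, comms)
        got = lc.modularity_q(make_graph(adj), lc.Partition.from_labels(labels))
        assert got == pytest.approx(expect, abs=1e-12)


class TestModularityExamples:
    def test_two_disjoint_triangles(self):
        adj = np.zeros((6, 6), dtype=bool)
        for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            adj[i, j] = adj[j, i] = True
        part = lc.Partition.from_labels([1, 1, 1, 2, 2, 2])
        assert lc.modularity_q(make_graph(adj), part) == pytest.approx(0.5, abs=1e-12)

    def test_single_module_gives_zero(self, rng):
        adj, _ = random_graph_and_partition(rng, 10)
        part = lc.Partition.from_labels([1] * 10)
        assert lc.modularity_q(make_graph(adj), part) == pytest.approx(0.0, abs=1e-12)

    def test_edgeless_graph_rejected(self):
        g = make_graph(np.zeros((4, 4), dtype=bool))
        with pytest.raises(UndefinedMetricError):
            lc.modularity_q(g, lc.Partition.from_labels([1, 1, 2, 2]))

    def test_within_only_edges_maximize_q(self):
        # exhaustive: among all 5-edge subgraphs of K6 under a 2-module
        # partition, a maximal-Q subgraph never uses an inter-module edge
        labels = [1, 1, 1, 2, 2, 2]
        part = lc.Partition.from_labels(labels)
        all_edges = list(combinations(range(6), 2))
        best_q, best_edges = -2.0, None
        for edges in combinations(all_edges, 5):
            adj = np.zeros((6, 6), dtype=bool)
            for i, j in edges:
                adj[i, j] = adj[j, i] = True
            q = lc.modularity_q(make_graph(adj), part)
            if q > best_q:
                best_q, best_edges = q, edges
        assert all(labels[i] == labels[j] for i, j in best_edges)


class TestParticipationCoefficient:
    def test_all_edges_within_module_gives_zero(self):
        adj = np.zeros((4, 4), dtype=bool)
        adj[0, 1] = adj[1, 0] = True
        part = lc.Partition.from_labels([1, 1, 2, 2])
        pc = lc.participation_coefficients(make_graph(adj), part)
        assert pc[0] == pytest.approx(0.0)

    def test_even_spread_over_three_modules(self):
        # node 0 with 2 edges into each of 3 foreign modules: PC = 1 - 3*(1/3)^2
        adj = np.zeros((7, 7), dtype=bool)
        for j in range(1, 7):
            adj[0, j] = adj[j, 0] = True
        part = lc.Partition.from_labels([4, 1, 1, 2, 2, 3, 3])
        pc = lc.participation_coefficients(make_graph(adj), part)
        assert pc[0] == pytest.approx(1 - 3 * (1 / 3) ** 2, abs=1e-12)

    def test_isolated_node_zero_by_convention(self):
        adj = np.zeros((3, 3), dtype=bool)
        adj[1, 2] = adj[2, 1] = True
        pc = lc.participation_coefficients(make_graph(adj), lc.Partition.from_labels([1, 1, 2]))
        assert pc[0] == 0.0

    def test_invariant_to_module_relabeling(self, rng):
        adj, labels = random_graph_and_partition(rng, 15)
        perm = {m: i + 1 for i, m in enumerate(np.random.default_rng(1).permutation(
            sorted(set(labels))))}
        relabeled = np.array([perm[m] for m in labels])
        g = make_graph(adj)
        np.testing.assert_allclose(
            lc.participation_coefficients(g, lc.Partition.from_labels(labels)),
            lc.participation_coefficients(g, lc.Partition.from_labels(relabeled)),
        )


class TestWithinModuleDegree:
    def test_uniform_module_gives_zero(self):
        # complete 4-node module: every within-degree equals 3, sigma = 0
        adj = np.zeros((4, 4), dtype=bool)
        for i, j in combinations(range(4), 2):
            adj[i, j] = adj[j, i] = True
        wd = lc.within_module_degree_z(
            make_graph(adj), lc.Partition.from_labels([1, 1, 1, 1])
        )
        np.testing.assert_array_equal(wd, np.zeros(4))

    def test_star_module_zscores(self):
        # 5-node module, hub 2 adjacent to all plus edge (0,1):
        # within-degrees {2,2,4,1,1}; z = (kappa - mu)/sigma, population SD
        adj = np.zeros((5, 5), dtype=bool)
        for i, j in [(2, 0), (2, 1), (2, 3), (2, 4), (0, 1)]:
            adj[i, j] = adj[j, i] = True
        wd = lc.within_module_degree_z(make_graph(adj), lc.Partition.from_labels([1] * 5))
        kappa = np.array([2, 2, 4, 1, 1])
        np.testing.assert_allclose(wd, (kappa - kappa.mean()) / kappa.std(), atol=1e-12)

    def test_isolated_member_gets_negative_z(self):
        # module {0..3} with within-degrees {1,2,2,3}: z-scores from the
        # population SD; node 0 below the module mean, node 3 above
        adj = np.zeros((4, 4), dtype=bool)
        for i, j in [(1, 2), (1, 3), (2, 3), (3, 0)]:
            adj[i, j] = adj[j, i] = True
        wd = lc.within_module_degree_z(make_graph(adj), lc.Partition.from_labels([1] * 4))
        kappa = np.array([1, 2, 2, 3])
        np.testing.assert_allclose(wd, (kappa - kappa.mean()) / kappa.std(), atol=1e-12)
        assert wd[0] < 0 < wd[3]

    def test_documented_zscore_magnitudes(self):
        # within-degree multisets {1,1,4} and {0,2,2,4} give +/-1.4142 at
        # the extremes under the population-SD convention
        k1 = np.array([1.0, 1.0, 4.0])
        assert (k1[2] - k1.mean()) / k1.std() == pytest.approx(1.4142, abs=1e-4)
        k2 = np.array([0.0, 2.0, 2.0, 4.0])
        assert (k2[0] - k2.mean()) / k2.std() == pytest.approx(-1.4142, abs=1e-4)

    def test_invariant_to_disconnected_extra_module(self, rng):
        adj, labels = random_graph_and_partition(rng, 12)
        g = make_graph(adj)
        wd = lc.within_module_degree_z(g, lc.Partition.from_labels(labels))
        # append two isolated nodes in a fresh module
        adj2 = np.zeros((14, 14), dtype=bool)
        adj2[:12, :12] = adj
        labels2 = np.concatenate([labels, [labels.max() + 1] * 2])
        wd2 = lc.within_module_degree_z(
            make_graph(adj2), lc.Partition.from_labels(labels2)
        )
        np.testing.assert_allclose(wd2[:12], wd)


class TestReferencePartition:
    def test_degenerate_cluster_counts(self, rng):
        avg = rng.normal(size=(8, 8))
        avg = (avg + avg.T) / 2
        p1 = lc.reference_partition(avg, 1)
        assert p1.n_modules == 1
        pn = lc.reference_partition(avg, 8)
        assert pn.n_modules == 8

    def test_two_planted_blocks_recovered_exactly(self):
        n = 12
        labels = np.array([1] * 6 + [2] * 6)
        same = labels[:, None] == labels[None, :]
        z = np.where(same, 0.8, 0.0)
        np.fill_diagonal(z, 0.0)
        for distance in ("correlation", "euclidean"):
            part = lc.reference_partition(z, 2, distance=distance)
            got = part.labels_for(np.arange(n))
            assert len(set(got[:6])) == 1 and len(set(got[6:])) == 1
            assert got[0] != got[6]
            assert got[0] == 1  # labels renumbered by first appearance

    def test_invalid_k_rejected(self, rng):
        avg = np.zeros((5, 5))
        for k in (0, 6):
            with pytest.raises(ParameterError):
                lc.reference_partition(avg, k)


class TestHubIdentification:
    def test_constant_values_give_empty_set(self):
        assert lc.identify_hubs({i: 0.5 for i in range(6)}) == set()

    def test_single_outlier(self):
        vals = {0: 0.0, 1: 0.0, 2: 0.0, 3: 0.0, 4: 10.0}
        assert lc.identify_hubs(vals) == {4}

    def test_linear_values(self):
        vals = {i: float(v) for i, v in enumerate([1, 2, 3, 4, 5])}
        assert lc.identify_hubs(vals) == {4}

    def test_too_few_values_rejected(self):
        with pytest.raises(DegenerateInputError):
            lc.identify_hubs({0: 1.0})


class TestHubTemplate:
    def make_series(self, d):
        import pandas as pd

        return pd.Series(d, dtype=float)

    def test_single_subject_passthrough(self):
        pc = self.make_series({0: 0.1, 1: 0.9, 2: 0.2})
        wd = self.make_series({0: -1.0, 1: 0.0, 2: 2.0})
        tpl = lc.build_hub_template([pc], [wd])
        assert tpl.pc_mean.loc[1] == pytest.approx(0.9)
        assert (tpl.n_contributing == 1).all()

    def test_mean_over_retaining_subjects(self):
        pcs = [self.make_series({0: 0.2, 1: 0.5}), self.make_series({0: 0.4, 2: 0.7})]
        wds = [self.make_series({0: 0.0, 1: 1.0}), self.make_series({0: 2.0, 2: -1.0})]
        tpl = lc.build_hub_template(pcs, wds)
        assert tpl.pc_mean.loc[0] == pytest.approx(0.3)  # both subjects
        assert tpl.pc_mean.loc[1] == pytest.approx(0.5)  # subject 0 only
        assert tpl.n_contributing.loc[0] == 2
        assert tpl.n_contributing.loc[1] == 1

    def test_template_frame_flags_hub_sets(self, default_world):
        df = default_world.template.to_frame()
        assert set(df.index[df.is_global_hub]) == default_world.template.global_hubs
        assert set(df.index[df.is_local_hub]) == default_world.template.local_hubs
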