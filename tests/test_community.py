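"""Clustering, cophenetic fidelity, modularity, and community selection."""

import io

import numpy as np
import pytest

from orcasoc import association as asc, community as comm
from conftest import cophenetic_bruteforce, modularity_bruteforce


def assoc_from_sri(sri: np.ndarray, ids=None) -> asc.AssociationMatrix:
    """Wrap a raw SRI-like matrix for clustering tests (counts synthesized)."""
    n = sri.shape[0]
    ids = ids or [f"W{k}" for k in range(n)]
    sri = sri.copy()
    np.fill_diagonal(sri, 1.0)
    counts = asc.PairCounts(ids=ids, X=np.eye(n, dtype=int), n=np.ones(n, dtype=int))
    return asc.AssociationMatrix(ids=ids, sri=sri, counts=counts)


def planted_blocks(rng, n=40, within=0.8, between=0.01, jitter=0.02):
    sri = np.full((n, n), between)
    half = n // 2
    sri[:half, :half] = within
    sri[half:, half:] = within
    noise = rng.uniform(-jitter, jitter, size=(n, n))
    noise = (noise + noise.T) / 2
    sri = np.clip(sri + noise, 0.0, 1.0)
    labels = [0] * half + [1] * (n - half)
    return assoc_from_sri(sri), labels


class TestAverageLinkage:
    def test_hand_worked_upgma(self):
        # d(A,B)=0.2, d(A,C)=d(B,C)=0.6 -> merge (A,B) at 0.2, then C at 0.6
        sri = 1.0 - np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]])
        dend = comm.average_linkage(assoc_from_sri(sri, ids=["A", "B", "C"]))
        assert dend.linkage[0, 2] == pytest.approx(0.2)
        assert dend.linkage[1, 2] == pytest.approx(0.6)
        assert set(dend.linkage[0, :2]) == {0.0, 1.0}

    def test_two_leaves_single_merge(self):
        sri = np.array([[1.0, 0.7], [0.7, 1.0]])
        dend = comm.average_linkage(assoc_from_sri(sri))
        assert dend.linkage.shape == (1, 4)
        assert dend.linkage[0, 2] == pytest.approx(0.3)

    def test_degenerate_equal_distances(self):
        sri = np.full((4, 4), 0.5)
        dend = comm.average_linkage(assoc_from_sri(sri))
        assert np.allclose(dend.heights, 0.5)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(0, 1, (12, 12))
        dend = comm.average_linkage(assoc_from_sri((m + m.T) / 2))
        assert (np.diff(dend.heights) >= -1e-12).all()

    def test_single_leaf_rejected(self):
        with pytest.raises(ValueError):
            comm.average_linkage(assoc_from_sri(np.array([[1.0]])))


class TestCopheneticCorrelation:
    def test_ultrametric_input_gives_one(self):
        # two tight pairs far apart: exactly representable by a tree
        d = np.array([
            [0.0, 0.1, 0.8, 0.8],
            [0.1, 0.0, 0.8, 0.8],
            [0.8, 0.8, 0.0, 0.2],
            [0.8, 0.8, 0.2, 0.0],
        ])
        a = assoc_from_sri(1 - d)
        assert comm.cophenetic_correlation(comm.average_linkage(a), a) == pytest.approx(1.0)

    def test_matches_bruteforce_pair_lookup(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            m = rng.uniform(0, 1, (4, 4))
            a = assoc_from_sri((m + m.T) / 2)
            dend = comm.average_linkage(a)
            coph = cophenetic_bruteforce(dend.linkage, 4)
            d = []
            for i in range(4):
                for j in range(i + 1, 4):
                    d.append(1 - a.sri[i, j])
            expected = np.corrcoef(np.array(d), coph)[0, 1]
            assert comm.cophenetic_correlation(dend, a) == pytest.approx(expected)

    def test_anticorrelated_tree_yields_negative_value(self):
        d = np.array([
            [0.0, 0.9, 0.1, 0.1],
            [0.9, 0.0, 0.1, 0.1],
            [0.1, 0.1, 0.0, 0.9],
            [0.1, 0.1, 0.9, 0.0],
        ])
        a_true = assoc_from_sri(1 - d)
        # a tree built from the *complemented* dissimilarities
        a_flip = assoc_from_sri(d.copy())
        dend = comm.average_linkage(a_flip)
        assert comm.cophenetic_correlation(dend, a_true) < 0

    def test_zero_variance_errors(self):
        a = assoc_from_sri(np.full((3, 3), 0.4))
        with pytest.raises(comm.UndefinedStatisticError):
            comm.cophenetic_correlation(comm.average_linkage(a), a)


class TestModularity:
    def test_single_cluster_is_zero(self):
        rng = np.random.default_rng(1)
        m = rng.uniform(0, 1, (8, 8))
        a = assoc_from_sri((m + m.T) / 2)
        assert comm.modularity({i: 0 for i in a.ids}, a) == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_dyads_give_half(self):
        sri = np.zeros((4, 4))
        sri[0, 1] = sri[1, 0] = 1.0
        sri[2, 3] = sri[3, 2] = 1.0
        a = assoc_from_sri(sri)
        part = {a.ids[0]: 0, a.ids[1]: 0, a.ids[2]: 1, a.ids[3]: 1}
        assert comm.modularity(part, a) == pytest.approx(0.5)

    def test_matches_double_sum_oracle_on_random_partitions(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = int(rng.integers(4, 12))
            m = rng.uniform(0, 1, (n, n))
            a = assoc_from_sri((m + m.T) / 2)
            part = {i: int(rng.integers(0, 3)) for i in a.ids}
            off = a.sri.copy()
            np.fill_diagonal(off, 0.0)
            assert comm.modularity(part, a) == pytest.approx(
                modularity_bruteforce(part, a.ids, off), abs=1e-10)

    def test_label_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        m = rng.uniform(0, 1, (10, 10))
        a = assoc_from_sri((m + m.T) / 2)
        part = {i: k % 3 for k, i in enumerate(a.ids)}
        relabeled = {i: {0: 7, 1: 5, 2: 9}[c] for i, c in part.items()}
        assert comm.modularity(part, a) == pytest.approx(comm.modularity(relabeled, a))

    def test_zero_weight_errors(self):
        a = assoc_from_sri(np.zeros((3, 3)))
        with pytest.raises(comm.UndefinedStatisticError):
            comm.modularity({i: 0 for i in a.ids}, a)


class TestBestPartition:
    def test_recovers_planted_blocks(self):
        rng = np.random.default_rng(6)
        a, labels = planted_blocks(rng)
        result = comm.best_partition(comm.average_linkage(a), a)
        found = [result.partition[i] for i in a.ids]
        groups = {(l, f) for l, f in zip(labels, found)}
        assert result.n_clusters == 2
        assert len(groups) == 2  # one-to-one label correspondence
        assert result.q_max > 0.3

    def test_uniform_matrix_selects_single_cluster(self):
        rng = np.random.default_rng(10)
        m = 0.5 + rng.uniform(-0.01, 0.01, (15, 15))
        a = assoc_from_sri((m + m.T) / 2)
        result = comm.best_partition(comm.average_linkage(a), a)
        assert result.n_clusters == 1
        assert result.q_max == pytest.approx(0.0, abs=0.02)

    def test_cut_trace_is_complete_and_qmax_dominates(self):
        rng = np.random.default_rng(12)
        a, _ = planted_blocks(rng, n=16)
        dend = comm.average_linkage(a)
        result = comm.best_partition(dend, a)
        distinct = set(np.round(dend.heights, 12))
        assert len(result.q_by_cut) == len(distinct) + 1
        assert any(k == len(a.ids) for _, k, _ in result.q_by_cut)
        assert all(q <= result.q_max + 1e-12 for _, _, q in result.q_by_cut)
        assert result.q_max == pytest.approx(max(q for _, _, q in result.q_by_cut))


class TestExport:
    def test_min_edge_one_keeps_constant_companions_only(self):
        sri = np.zeros((3, 3))
        sri[0, 1] = sri[1, 0] = 1.0
        sri[1, 2] = sri[2, 1] = 0.4
        a = assoc_from_sri(sri)
        result = comm.best_partition(comm.average_linkage(a), a)
        g = comm.export_network(a, result, min_edge=1.0)
        assert set(g.edges) == {(a.ids[0], a.ids[1])}

    def test_min_edge_zero_gives_all_nonzero_pairs(self):
        rng = np.random.default_rng(13)
        m = rng.uniform(0.1, 1, (6, 6))
        a = assoc_from_sri((m + m.T) / 2)
        result = comm.best_partition(comm.average_linkage(a), a)
        g = comm.export_network(a, result, min_edge=0.0)
        assert g.number_of_edges() == 15

    def test_graphml_round_trip_preserves_weights(self, tmp_path):
        import networkx as nx

        rng = np.random.default_rng(14)
        m = rng.uniform(0, 1, (5, 5))
        a = assoc_from_sri((m + m.T) / 2)
        result = comm.best_partition(comm.average_linkage(a), a)
        path = tmp_path / "net.graphml"
        g = comm.export_network(a, result, 0.0, path)
        g2 = nx.read_graphml(path)
        for u, v, data in g.edges(data=True):
            assert g2[u][v]["weight"] == pytest.approx(data["weight"])
        for node in g:
            assert int(g2.nodes[node]["cluster"]) == g.nodes[node]["cluster"]

    def test_newick_parses_with_all_leaves(self):
        from Bio import Phylo

        rng = np.random.default_rng(15)
        m = rng.uniform(0, 1, (7, 7))
        a = assoc_from_sri((m + m.T) / 2)
        dend = comm.average_linkage(a)
        tree = Phylo.read(io.StringIO(comm.to_newick(dend)), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(a.ids)
        # root-to-leaf depth equals the root merge height for every leaf
        depths = tree.depths()
        root_h = dend.heights[-1]
        for leaf in tree.get_terminals():
            assert depths[leaf] == pytest.approx(root_h, abs=1e-6)
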