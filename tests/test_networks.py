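import itertools

import numpy as np
import pytest

from socspat import (
    AssociationMatrix,
    affiliative_network,
    affiliative_network_excluding_zone,
    association_matrix_from_graphs,
    cooccurrence_network,
    half_weight_index,
    modularity_q,
    newman_communities,
    per_scan_association_graphs,
    permutation_test_nonrandom_association,
)
from socspat.networks import ScanGraph

from conftest import make_scan_table

DOOR = (5.5, 3.5)


class TestPerScanGraphs:
    def test_one_metre_inclusive(self):
        table = make_scan_table([(1, "15:00", "a", 3.5, 4.5), (1, "15:00", "b", 3.5, 5.5)])
        (g,) = per_scan_association_graphs(table)
        assert g.edges == {("a", "b")}

    def test_diagonal_neighbours_not_associated(self):
        table = make_scan_table([(1, "15:00", "a", 3.5, 4.5), (1, "15:00", "b", 4.5, 5.5)])
        (g,) = per_scan_association_graphs(table)
        assert g.edges == set()

    def test_single_individual_no_dyads(self):
        table = make_scan_table([(1, "15:00", "a", 3.5, 4.5)])
        (g,) = per_scan_association_graphs(table)
        assert g.observed == ["a"] and g.edges == set()

    def test_strictly_pairwise_no_chaining(self):
        # a-b and b-c within 1 m but a-c at 2 m: a-c not associated
        table = make_scan_table(
            [(1, "15:00", "a", 3.5, 4.5), (1, "15:00", "b", 3.5, 5.5), (1, "15:00", "c", 3.5, 6.5)]
        )
        (g,) = per_scan_association_graphs(table)
        assert ("a", "c") not in g.edges and len(g.edges) == 2


class TestHalfWeightIndex:
    def test_direct_formula(self):
        assert half_weight_index(2, 1, 1, 0) == pytest.approx(2 / 3)

    def test_never_associated(self):
        assert half_weight_index(0, 3, 2, 4) == 0.0

    def test_always_together(self):
        assert half_weight_index(5, 0, 0, 0) == 1.0

    def test_never_sampled_is_missing(self):
        assert np.isnan(half_weight_index(0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            half_weight_index(-1, 0, 0, 0)


class TestAssociationMatrix:
    def _graphs(self):
        return [
            ScanGraph(1, ["a", "b", "c"], {("a", "b")}),
            ScanGraph(2, ["a", "b"], set()),
            ScanGraph(3, ["a"], set()),
            ScanGraph(4, ["b", "c"], {("b", "c")}),
        ]

    def test_counts_and_hwi(self):
        m = association_matrix_from_graphs(self._graphs(), ["a", "b", "c"], "affiliative_1m")
        ia, ib = 0, 1
        # a,b: x=1, both observed twice (yAB=1), a alone once, b alone once
        assert m.x[ia, ib] == 1
        assert m.y_ab[ia, ib] == 1
        assert m.y_a[ia, ib] == 1 and m.y_b[ia, ib] == 1
        assert m.hwi[ia, ib] == pytest.approx(1 / (1 + 1 + 1))

    def test_scan_order_invariance(self):
        ids = ["a", "b", "c"]
        base = association_matrix_from_graphs(self._graphs(), ids, "affiliative_1m")
        rev = association_matrix_from_graphs(self._graphs()[::-1], ids, "affiliative_1m")
        np.testing.assert_allclose(base.hwi, rev.hwi)

    def test_label_equivariance(self):
        ids = ["a", "b", "c"]
        base = association_matrix_from_graphs(self._graphs(), ids, "affiliative_1m")
        perm = [2, 0, 1]
        permuted = association_matrix_from_graphs(
            self._graphs(), [ids[k] for k in perm], "affiliative_1m"
        )
        np.testing.assert_allclose(permuted.hwi, base.hwi[np.ix_(perm, perm)])

    def test_symmetry_and_range(self, small_dataset):
        ids = list(small_dataset.latent.dominance.index)
        m = affiliative_network(small_dataset.scans, ids)
        vals = m.hwi[~np.isnan(m.hwi)]
        assert (vals >= 0).all() and (vals <= 1).all()
        np.testing.assert_allclose(m.hwi, m.hwi.T, equal_nan=True)


class TestZoneNetworks:
    def test_three_in_zone_three_dyads(self):
        table = make_scan_table(
            [
                (1, "15:00", "a", 5.5, 3.5),
                (1, "15:00", "b", 5.5, 6.5),
                (1, "15:00", "c", 7.5, 3.5),
                (1, "15:00", "d", 25.5, 25.5),
            ]
        )
        m = cooccurrence_network(table, ["a", "b", "c", "d"], DOOR)
        assert m.x.sum() / 2 == 3
        assert m.x[0, 3] == 0

    def test_beyond_radius_never_counted(self):
        table = make_scan_table([(1, "15:00", "a", 5.5, 9.5), (1, "15:00", "b", 5.5, 3.5)])
        m = cooccurrence_network(table, ["a", "b"], DOOR, radius=5.0)
        assert m.x.sum() == 0  # a is 6 m from the door

    def test_nobody_in_zone_zero_matrix(self):
        table = make_scan_table([(1, "15:00", "a", 25.5, 25.5), (1, "15:00", "b", 27.5, 25.5)])
        m = cooccurrence_network(table, ["a", "b"], DOOR)
        assert m.x.sum() == 0

    def test_exclusion_all_at_door_empties_network(self):
        table = make_scan_table([(1, "15:00", "a", 5.5, 3.5), (1, "15:00", "b", 5.5, 4.5)])
        m = affiliative_network_excluding_zone(table, ["a", "b"], DOOR)
        assert m.x.sum() == 0

    def test_exclusion_far_from_door_is_identity(self):
        table = make_scan_table([(1, "15:00", "a", 20.5, 20.5), (1, "15:00", "b", 20.5, 21.5)])
        full = affiliative_network(table, ["a", "b"])
        excl = affiliative_network_excluding_zone(table, ["a", "b"], DOOR)
        np.testing.assert_allclose(full.hwi, excl.hwi, equal_nan=True)

    def test_exclusion_matches_brute_force(self, small_dataset):
        ids = list(small_dataset.latent.dominance.index)
        excl = affiliative_network_excluding_zone(small_dataset.scans, ids, DOOR)
        # brute force: recount 1-m dyads skipping pairs both within 5 m
        vis = small_dataset.scans.df[small_dataset.scans.df["visible"]]
        index = {ind: k for k, ind in enumerate(ids)}
        x = np.zeros((len(ids), len(ids)))
        for _, grp in vis.groupby("scan_id"):
            rows = list(grp.itertuples())
            for r1, r2 in itertools.combinations(rows, 2):
                d = np.hypot(r1.x - r2.x, r1.y - r2.y)
                z1 = np.hypot(r1.x - DOOR[0], r1.y - DOOR[1]) <= 5
                z2 = np.hypot(r2.x - DOOR[0], r2.y - DOOR[1]) <= 5
                if d <= 1.0 and not (z1 and z2):
                    i, j = index[r1.individual], index[r2.individual]
                    x[i, j] += 1
                    x[j, i] += 1
        np.testing.assert_allclose(excl.x, x)


class TestPermutationTest:
    def _random_graphs(self, rng, n_ind=8, n_scans=15, p_obs=0.75, p_edge=0.25):
        ids = [f"i{k}" for k in range(n_ind)]
        graphs = []
        for s in range(n_scans):
            obs = [i for i in ids if rng.random() < p_obs]
            edges = {
                (a, b)
                for a, b in itertools.combinations(sorted(obs), 2)
                if rng.random() < p_edge
            }
            graphs.append(ScanGraph(s, obs, edges))
        return ids, graphs

    def test_preserves_degrees_and_edge_counts(self):
        rng = np.random.default_rng(0)
        ids, graphs = self._random_graphs(rng)
        # the _check_invariants hook asserts per-scan degree sequences and
        # edge counts on every permuted replicate
        permutation_test_nonrandom_association(
            graphs, ids, n_perm=50, seed=1, burn_in_per_edge=5,
            thin_per_edge=1.0, _check_invariants=True,
        )

    def test_planted_preference_detected(self):
        rng = np.random.default_rng(2)
        ids = [f"i{k}" for k in range(8)]
        graphs = []
        pairs = [("i0", "i1"), ("i2", "i3"), ("i4", "i5")]
        for s in range(30):
            obs = [i for i in ids if rng.random() < 0.9]
            edges = {p for p in pairs if p[0] in obs and p[1] in obs}
            # one random extra edge to keep swaps possible
            extra = tuple(sorted(rng.choice([i for i in obs], 2, replace=False)))
            if extra[0] != extra[1]:
                edges.add(extra)
            graphs.append(ScanGraph(s, obs, edges))
        res = permutation_test_nonrandom_association(
            graphs, ids, n_perm=200, seed=3, burn_in_per_edge=20, thin_per_edge=2.0
        )
        assert res.p < 0.01

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        ids, graphs = self._random_graphs(rng)
        import copy

        r1 = permutation_test_nonrandom_association(
            copy.deepcopy(graphs), ids, n_perm=100, seed=7, burn_in_per_edge=5)
        r2 = permutation_test_nonrandom_association(
            copy.deepcopy(graphs), ids, n_perm=100, seed=7, burn_in_per_edge=5)
        assert r1.p == r2.p and r1.observed == r2.observed

    def test_no_structure_warns_p_one(self):
        graphs = [ScanGraph(1, ["a", "b"], {("a", "b")})]
        with pytest.warns(UserWarning):
            res = permutation_test_nonrandom_association(graphs, ["a", "b"], n_perm=10, seed=0)
        assert res.p == 1.0


def _assoc(ids, w):
    w = np.asarray(w, dtype=float)
    return AssociationMatrix(ids, w, "affiliative_1m", w, w * 0, w * 0, w * 0)


class TestModularity:
    def test_two_cliques_q_half(self):
        w = np.zeros((8, 8))
        for grp in (range(4), range(4, 8)):
            for i in grp:
                for j in grp:
                    if i != j:
                        w[i, j] = 1.0
        part = newman_communities(_assoc([f"i{k}" for k in range(8)], w))
        assert part.n_communities == 2
        assert part.q == pytest.approx(0.5)
        labels = part.assignment.to_numpy()
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1

    def test_complete_graph_single_community(self):
        w = np.ones((6, 6)) - np.eye(6)
        part = newman_communities(_assoc([f"i{k}" for k in range(6)], w))
        assert part.n_communities == 1

    def test_empty_network_errors(self):
        with pytest.raises(ValueError):
            newman_communities(_assoc(["a", "b"], np.zeros((2, 2))))

    def test_exhaustive_oracle_small_graphs(self):
        # found Q within 5% of the best partition into <= 3 groups
        rng = np.random.default_rng(10)
        for trial in range(5):
            n = 7
            w = rng.random((n, n)) * (rng.random((n, n)) < 0.45)
            w = np.triu(w, 1)
            w = w + w.T
            if w.sum() == 0:
                continue
            part = newman_communities(_assoc([f"i{k}" for k in range(n)], w))
            best = -1.0
            for labels in itertools.product(range(3), repeat=n):
                best = max(best, modularity_q(w, np.array(labels)))
            assert part.q >= 0.95 * best - 1e-9

    def test_agrees_with_igraph_leading_eigenvector(self, small_dataset):
        igraph = pytest.importorskip("igraph")
        ids = list(small_dataset.latent.dominance.index)
        m = affiliative_network(small_dataset.scans, ids)
        w = np.nan_to_num(m.hwi)
        part = newman_communities(m)
        g = igraph.Graph.Weighted_Adjacency(w.tolist(), mode="undirected")
        ref = g.community_leading_eigenvector(weights="weight")
        ref_q = g.modularity(ref.membership, weights="weight")
        assert part.q >= 0.95 * ref_q

    def test_planted_subgroups_recovered(self, small_dataset):
        sklearn = pytest.importorskip("sklearn.metrics")
        ids = list(small_dataset.latent.dominance.index)
        part = newman_communities(affiliative_network(small_dataset.scans, ids))
        ari = sklearn.adjusted_rand_score(
            small_dataset.latent.subgroup.to_numpy(), part.assignment.to_numpy()
        )
        assert ari >= 0.9
        assert part.q > 0.3
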