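"""Clustering, representative substructures, and differential testing."""

import math

import numpy as np
import pandas as pd
import pytest

from glycomotif.glycan_io import GlycanTree, Linkage, Monosaccharide
from glycomotif.motif_analysis import (
    bonferroni_criterion,
    cluster,
    cluster_abundance,
    collapse_network_by_clusters,
    correlation_distance_matrix,
    differential_test,
    representative_substructure,
    zscore_vs_reference,
    ClusterAssignment,
)
from glycomotif.network import build_network
from glycomotif.substructure import SubstructureProfile, SubstructureSet

from conftest import chain


class TestCluster:
    def test_perfectly_correlated_items_merge(self):
        m = pd.DataFrame([[1.0, 2, 3], [2.0, 4, 6]], index=["a", "b"])
        assign = cluster(m, cut=0.1)
        assert assign.n_clusters() == 1

    def test_anticorrelated_items_split(self):
        m = pd.DataFrame([[1.0, 2, 3], [3.0, 2, 1]], index=["a", "b"])
        assign = cluster(m, cut=0.5)
        assert assign.n_clusters() == 2

    def test_hand_computed_three_item_grouping(self, rng):
        base = rng.normal(size=50)
        a = base + rng.normal(scale=0.25, size=50)   # r(a, base) ~ 0.97
        c = rng.normal(size=50)                       # independent
        m = pd.DataFrame([base, a, c], index=["base", "a", "c"])
        d, _ = correlation_distance_matrix(m.to_numpy())
        assert d[0, 1] < 0.5 < d[0, 2]
        groups = cluster(m, cut=0.5).groups()
        parts = {frozenset(v) for v in groups.values()}
        assert frozenset({"base", "a"}) in parts and frozenset({"c"}) in parts

    def test_affine_rescaling_invariance(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 30)),
                         index=[f"i{k}" for k in range(5)])
        scaled = m.mul(pd.Series([2, 5, 0.3, 7, 1.5], index=m.index), axis=0).add(
            pd.Series([1, -3, 0, 10, 2], index=m.index), axis=0
        )
        assert cluster(m, cut=0.5).labels == cluster(scaled, cut=0.5).labels

    def test_zero_variance_item_flagged_not_crashing(self):
        m = pd.DataFrame([[1.0, 2, 3], [5.0, 5, 5]], index=["a", "flat"])
        assign = cluster(m, cut=0.5)
        assert assign.degenerate_items == ["flat"]
        assert assign.n_clusters() == 2

    def test_elbow_finds_planted_cluster_count(self, rng):
        centers = rng.normal(size=(2, 40)) * 5
        rows, names = [], []
        for ci in range(2):
            for j in range(5):
                rows.append(centers[ci] + rng.normal(scale=0.3, size=40))
                names.append(f"c{ci}_{j}")
        assign = cluster(pd.DataFrame(rows, index=names), cut="elbow")
        assert assign.n_clusters() == 2
        groups = {frozenset(v) for v in assign.groups().values()}
        assert frozenset(n for n in names if n.startswith("c0")) in groups


def _branch(symbols_positions) -> GlycanTree:
    """Star around root A with (symbol, parent_pos) children."""
    nodes = {1: Monosaccharide("A", "b")}
    edges = []
    for i, (sym, pos) in enumerate(symbols_positions, start=2):
        nodes[i] = Monosaccharide(sym, "b")
        edges.append((1, i, Linkage(pos, 1)))
    return GlycanTree(nodes, edges)


class TestRepresentative:
    def test_identical_members_reproduce_tree(self):
        t = chain("ABC")
        rep = representative_substructure([t, t, t], [1.0, 1.0, 1.0])
        assert rep.consensus.key == t.key
        assert all(f == pytest.approx(1.0) for f in rep.position_fractions.values())

    def test_three_of_four_members_keep_terminal_residue(self):
        with_b = _branch([("B", 3), ("C", 6)])
        without_b = _branch([("C", 6)])
        rep = representative_substructure(
            [with_b, with_b, with_b, without_b], [1, 1, 1, 1]
        )
        symbols = {m.symbol for m in rep.consensus.nodes.values()}
        assert symbols == {"A", "B", "C"}  # B at fraction 0.75 > 0.51

    def test_half_weight_residue_dropped_at_default_threshold(self):
        with_b = _branch([("B", 3)])
        without_b = _branch([])
        rep = representative_substructure([with_b, without_b], [1, 1])
        assert {m.symbol for m in rep.consensus.nodes.values()} == {"A"}

    def test_threshold_zero_gives_union_and_near_one_intersection(self):
        m1 = _branch([("B", 3)])
        m2 = _branch([("C", 6)])
        union = representative_substructure([m1, m2], [1, 1], threshold=0.0)
        inter = representative_substructure([m1, m2], [1, 1], threshold=1 - 1e-9)
        assert {m.symbol for m in union.consensus.nodes.values()} == {"A", "B", "C"}
        assert {m.symbol for m in inter.consensus.nodes.values()} == {"A"}

    def test_weights_shift_the_consensus(self):
        with_b = _branch([("B", 3)])
        without_b = _branch([])
        heavy = representative_substructure([with_b, without_b], [3, 1])
        light = representative_substructure([with_b, without_b], [1, 3])
        assert {m.symbol for m in heavy.consensus.nodes.values()} == {"A", "B"}
        assert {m.symbol for m in light.consensus.nodes.values()} == {"A"}

    def test_incompatible_roots_error(self):
        with pytest.raises(ValueError, match="incompatible roots"):
            representative_substructure([chain("AB"), chain("BA")], [1, 1])


class TestClusterAbundance:
    def _profiles(self):
        return [
            SubstructureProfile("s1", {"m1": 0.9, "m2": 0.3}),
            SubstructureProfile("s2", {"m1": 0.1, "m2": 0.1}),
        ]

    def test_weighted_mean(self):
        ab = cluster_abundance(["m1", "m2"], [2.0, 1.0], self._profiles())
        assert ab["s1"] == pytest.approx(0.7)

    def test_singleton_passthrough_and_zero(self):
        ab = cluster_abundance(["m2"], [5.0], self._profiles())
        assert ab["s1"] == pytest.approx(0.3)
        zeros = [SubstructureProfile("s", {"m1": 0.0, "m2": 0.0})]
        assert cluster_abundance(["m1", "m2"], [1, 1], zeros)["s"] == 0.0

    def test_empty_cluster_error(self):
        with pytest.raises(ValueError):
            cluster_abundance([], [], self._profiles())


class TestZScore:
    def test_reference_maps_to_zero_and_unit_spacing(self):
        z, degenerate = zscore_vs_reference(
            pd.Series({"a": 1.0, "ref": 2.0, "c": 3.0}), "ref"
        )
        assert not degenerate
        assert z["ref"] == 0.0
        assert z["a"] == pytest.approx(-1.0) and z["c"] == pytest.approx(1.0)

    def test_constant_vector_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            z, degenerate = zscore_vs_reference(
                pd.Series({"a": 2.0, "ref": 2.0}), "ref"
            )
        assert degenerate and (z == 0).all()

    def test_missing_reference_error(self):
        with pytest.raises(KeyError):
            zscore_vs_reference(pd.Series({"a": 1.0, "b": 2.0}), "zz")


class TestDifferential:
    def test_bonferroni_criterion_16_tests(self):
        assert bonferroni_criterion(0.05, 16) == pytest.approx(0.003125)
        assert round(bonferroni_criterion(0.05, 16), 4) == 0.0031

    def test_all_zero_differences_not_significant(self):
        res = differential_test(np.ones(8), np.ones(8), n_tests=16)
        assert res.p == 1.0 and res.effect_size_r == 0.0 and not res.significant

    def test_uniform_shift_exact_tail_and_effect_size(self):
        # 20 members shifted +1: one-sided exact p = 2^-20, r near 1
        res = differential_test(
            np.arange(20) + 1.0, np.arange(20) * 1.0, alternative="greater",
            n_tests=16,
        )
        assert res.p == pytest.approx(2.0**-20)
        assert res.significant
        assert res.effect_size_r > 0.68

    def test_one_sided_direction(self):
        lower = np.zeros(10)
        higher = np.ones(10)
        res_wrong = differential_test(lower, higher, alternative="greater")
        res_right = differential_test(lower, higher, alternative="less")
        assert res_right.p < 0.01 < res_wrong.p

    def test_small_membership_rejected(self):
        with pytest.raises(ValueError):
            differential_test(np.ones(4), np.zeros(4))

    def test_null_type_one_error_controlled(self, rng):
        alpha, hits, reps = 0.05, 0, 400
        for _ in range(reps):
            a = rng.normal(size=12)
            b = rng.normal(size=12)
            res = differential_test(a, b, alternative="greater")
            hits += res.p < alpha
        assert hits / reps <= alpha + 2.5 * math.sqrt(alpha * (1 - alpha) / reps)


class TestCollapse:
    def _net(self):
        trees = [chain("A"), chain("AB"), chain("ABC")]
        S = SubstructureSet()
        for t in trees:
            S.add(t)
        return build_network(S.sorted()), [t.key for t in trees]

    def test_identity_when_singletons(self):
        net, keys = self._net()
        assign = ClusterAssignment(items=keys, labels=[1, 2, 3], cut=0.5)
        g = collapse_network_by_clusters(net, assign)
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 2

    def test_single_cluster_drops_self_loops(self):
        net, keys = self._net()
        assign = ClusterAssignment(items=keys, labels=[1, 1, 1], cut=0.5)
        g = collapse_network_by_clusters(net, assign)
        assert g.number_of_nodes() == 1 and g.number_of_edges() == 0

    def test_two_cluster_path(self):
        net, keys = self._net()
        assign = ClusterAssignment(items=keys, labels=[1, 1, 2], cut=0.5)
        g = collapse_network_by_clusters(net, assign)
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 1
        assert g.nodes[1]["size"] == 2
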