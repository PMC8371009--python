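"""Network construction, enzyme annotation, and lossless motif pruning."""

import numpy as np
import pytest

from glycomotif.glycan_io import (
    GlycanTree,
    Glycoprofile,
    Linkage,
    Monosaccharide,
    parse_glycoct,
)
from glycomotif.network import (
    EnzymeRule,
    NetworkError,
    annotate_enzymes,
    build_network,
    coverage_fraction,
    default_enzyme_rules,
    load_enzyme_rules,
    motif_profile,
    reconstruct_profile,
    sample_occurrence,
    select_glyco_motifs,
    UNANNOTATED,
)
from glycomotif.substructure import (
    SubstructureProfile,
    SubstructureSet,
    build_substructure_set,
    contains,
    enumerate_substructures,
    substructure_profiles,
)

from conftest import chain, random_tree


def _set_of(trees) -> SubstructureSet:
    S = SubstructureSet()
    for t in trees:
        S.add(t)
    return S.sorted()


class TestBuildNetwork:
    def test_two_node_chain(self):
        S = _set_of([chain("A"), chain("AB")])
        net = build_network(S)
        assert list(net.graph.edges) == [(chain("A").key, chain("AB").key)]

    def test_linear_closure_is_path_graph(self):
        trees = [chain("ABCDE"[: i + 1]) for i in range(5)]
        net = build_network(_set_of(trees))
        assert net.graph.number_of_edges() == 4
        assert all(net.graph.out_degree(k) <= 1 for k in net.graph.nodes)

    def test_edges_equal_quadratic_containment_oracle(self, rng):
        for _ in range(10):
            t = random_tree(rng, int(rng.integers(3, 8)))
            S = enumerate_substructures(t)
            net = build_network(S)
            expected = set()
            for pk, ptree in S.members.items():
                for ck, ctree in S.members.items():
                    if len(ctree) == len(ptree) + 1 and contains(ctree, ptree) > 0:
                        expected.add((pk, ck))
            assert set(net.graph.edges) == expected

    def test_closure_violation_raises(self):
        S = _set_of([chain("A"), chain("ABC")])  # missing AB level
        with pytest.raises(NetworkError, match="closure"):
            build_network(S)

    def test_level_increases_by_one_along_every_edge(self, rng):
        t = random_tree(rng, 7)
        net = build_network(enumerate_substructures(t))
        for u, v in net.graph.edges:
            assert net.level(v) == net.level(u) + 1


def _gal() -> GlycanTree:
    return GlycanTree({1: Monosaccharide("Gal", "b")}, [])


def _with_child(tree: GlycanTree, symbol, anomer, ppos, cpos=1) -> GlycanTree:
    new = max(tree.nodes) + 1
    nodes = dict(tree.nodes)
    nodes[new] = Monosaccharide(symbol, anomer)
    return GlycanTree(nodes, list(tree.edges) + [(tree.root, new, Linkage(ppos, cpos))])


class TestAnnotateEnzymes:
    def test_sialylation_and_lacnac_extension_labels(self):
        gal = _gal()
        sia = _with_child(gal, "Neu5Ac", "a", 3, 2)
        gnt = _with_child(gal, "GlcNAc", "b", 3, 1)
        S = _set_of([gal, sia, gnt])
        net = build_network(S)
        rules = default_enzyme_rules("nglycan")
        annotate_enzymes(net, rules)
        assert net.graph.edges[gal.key, sia.key]["enzyme"] == "a3SiaT"
        assert net.graph.edges[gal.key, gnt.key]["enzyme"] == "iGnT"

    def test_uncovered_edge_is_unannotated(self):
        gal = _gal()
        xyl = _with_child(gal, "Xyl", "b", 2)
        net = build_network(_set_of([gal, xyl]))
        annotate_enzymes(net, default_enzyme_rules("nglycan"))
        assert net.graph.edges[gal.key, xyl.key]["enzyme"] == UNANNOTATED

    def test_ambiguous_rules_error_lists_both(self):
        gal = _gal()
        sia = _with_child(gal, "Neu5Ac", "a", 3, 2)
        net = build_network(_set_of([gal, sia]))
        rules = [
            EnzymeRule("EnzA", "Neu5Ac", "a", 3, 2),
            EnzymeRule("EnzB", "Neu5Ac", "a", 3, None),
        ]
        with pytest.raises(NetworkError, match="EnzA.*EnzB"):
            annotate_enzymes(net, rules)

    def test_yaml_round_trip(self):
        text = (
            "- {enzyme: T1, residue: Gal, anomer: b, parent_pos: 4, "
            "child_pos: 1, context: GlcNAc}\n"
        )
        (rule,) = load_enzyme_rules(text)
        assert rule.enzyme == "T1" and rule.context.nodes[1].symbol == "GlcNAc"


def _profiles_from_values(keys, matrix) -> list[SubstructureProfile]:
    return [
        SubstructureProfile(f"s{i+1}", dict(zip(keys, row)))
        for i, row in enumerate(matrix)
    ]


class TestSelectGlycoMotifs:
    def test_identical_chain_prunes_parent_weight_two(self):
        a, ab = chain("A"), chain("AB")
        net = build_network(_set_of([a, ab]))
        profiles = _profiles_from_values([a.key, ab.key], [[0.7, 0.7], [0.2, 0.2]])
        select_glyco_motifs(net, profiles)
        assert not net.is_motif(a.key) and net.is_motif(ab.key)
        assert net.weight(ab.key) == pytest.approx(2.0)
        assert net.total_weight() == pytest.approx(2.0)

    def test_differing_chain_keeps_both(self):
        a, ab = chain("A"), chain("AB")
        net = build_network(_set_of([a, ab]))
        profiles = _profiles_from_values([a.key, ab.key], [[0.7, 0.5]])
        select_glyco_motifs(net, profiles)
        assert net.is_motif(a.key) and net.is_motif(ab.key)
        assert net.weight(a.key) == net.weight(ab.key) == 1.0

    def test_equal_division_over_matching_children(self):
        a = chain("A")
        kids = [chain("AB"), chain("AC"), chain("AD")]
        net = build_network(_set_of([a] + kids))
        keys = [a.key] + [k.key for k in kids]
        # parent matches first two children, third differs
        profiles = _profiles_from_values(keys, [[0.9, 0.9, 0.9, 0.4]])
        select_glyco_motifs(net, profiles)
        assert not net.is_motif(a.key)
        assert net.weight(kids[0].key) == pytest.approx(1.5)
        assert net.weight(kids[1].key) == pytest.approx(1.5)
        assert net.weight(kids[2].key) == pytest.approx(1.0)
        assert net.total_weight() == pytest.approx(4.0)

    def test_negative_tolerance_rejected(self):
        a, ab = chain("A"), chain("AB")
        net = build_network(_set_of([a, ab]))
        with pytest.raises(ValueError):
            select_glyco_motifs(net, _profiles_from_values([a.key, ab.key], [[1, 1]]), tol=-1)

    def test_motif_minimality_no_identical_pair_remains(self, rng):
        for _ in range(15):
            t = random_tree(rng, int(rng.integers(3, 8)))
            glycans = list(enumerate_substructures(t))
            w = rng.dirichlet(np.ones(len(glycans)))
            prof = Glycoprofile(
                "s1",
                {g.key: float(x) for g, x in zip(glycans, w)},
                {g.key: g for g in glycans},
            )
            S = build_substructure_set([prof])
            sps = substructure_profiles([prof], S)
            net = select_glyco_motifs(build_network(S), sps)
            vec = {k: np.array([p.values[k] for p in sps]) for k in net.graph.nodes}
            for u, v in net.graph.edges:
                if net.is_motif(u) and net.is_motif(v):
                    assert not np.allclose(vec[u], vec[v], rtol=1e-9, atol=1e-9)


class TestReconstruction:
    def _pipeline(self, rng, n_profiles=3):
        t = random_tree(rng, int(rng.integers(4, 8)))
        glycans = list(enumerate_substructures(t))
        profs = []
        for i in range(n_profiles):
            w = rng.dirichlet(np.ones(len(glycans)))
            profs.append(
                Glycoprofile(
                    f"s{i}",
                    {g.key: float(x) for g, x in zip(glycans, w)},
                    {g.key: g for g in glycans},
                )
            )
        S = build_substructure_set(profs)
        sps = substructure_profiles(profs, S)
        net = select_glyco_motifs(build_network(S), sps)
        return net, sps

    def test_reconstruct_inverts_restriction(self, rng):
        for _ in range(10):
            net, sps = self._pipeline(rng)
            for sp in sps:
                rec = reconstruct_profile(motif_profile(sp, net), net)
                for k, v in sp.values.items():
                    assert rec.values[k] == pytest.approx(v, abs=1e-9)

    def test_identity_when_nothing_pruned(self):
        a, ab = chain("A"), chain("AB")
        net = build_network(_set_of([a, ab]))
        sps = _profiles_from_values([a.key, ab.key], [[0.9, 0.4]])
        select_glyco_motifs(net, sps)
        rec = reconstruct_profile(motif_profile(sps[0], net), net)
        assert rec.values == sps[0].values

    def test_missing_merge_trace_errors(self):
        a, ab = chain("A"), chain("AB")
        net = build_network(_set_of([a, ab]))
        sps = _profiles_from_values([a.key, ab.key], [[0.5, 0.5]])
        select_glyco_motifs(net, sps)
        net.merge_trace.clear()  # corrupt the audit trail
        from glycomotif.network import MotifProfile

        with pytest.raises(NetworkError, match="merge trace"):
            reconstruct_profile(MotifProfile("s1", {ab.key: 0.5}), net)


class TestCoverageOccurrence:
    def test_full_and_fractional_coverage(self):
        trees = [chain("A"), chain("AB"), chain("ABC")]
        net = build_network(_set_of(trees))
        full = SubstructureProfile("s", {t.key: 0.5 for t in trees})
        assert coverage_fraction(full, net) == 1.0
        one = Glycoprofile(
            "s", {chain("A").key: 1.0}, {chain("A").key: chain("A")}
        )
        assert coverage_fraction(one, net) == pytest.approx(1 / 3)

    def test_empty_network_error(self):
        import networkx as nx
        from glycomotif.network import SubstructureNetwork

        empty = SubstructureNetwork(nx.DiGraph(), 1)
        with pytest.raises(NetworkError):
            coverage_fraction(SubstructureProfile("s", {}), empty)

    def test_occurrence_proportions(self):
        p1 = SubstructureProfile("s1", {"x": 0.5, "y": 0.0})
        p2 = SubstructureProfile("s2", {"x": 0.1, "y": 0.3})
        occ = sample_occurrence([p1, p2])
        assert occ["x"] == 1.0 and occ["y"] == 0.5

    def test_substructures_less_sparse_than_glycans(self, rng):
        # decomposition shares substructures across samples, so mean
        # occurrence can only grow relative to whole glycans
        from glycomotif.synthetic import SimulationConfig, knockout_panel

        panel = knockout_panel(seed=11, samples_per_condition=1, max_size=6)
        profs = [p for res in panel.values() for p in res.profiles]
        S = build_substructure_set(profs)
        sps = substructure_profiles(profs, S)
        g_occ = np.mean(list(sample_occurrence(profs).values()))
        s_occ = np.mean(list(sample_occurrence(sps).values()))
        assert s_occ >= g_occ
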