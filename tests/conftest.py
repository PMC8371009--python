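"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own canonical-key and
matching machinery: isomorphism is decided by backtracking over child
permutations, substructure enumeration by scanning all node subsets, and
embedding counting by exhaustive injective assignment.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from glycomotif.glycan_io import GlycanTree, Linkage, Monosaccharide


# ---------------------------------------------------------------------------
# random structure generation


def random_tree(
    rng: np.random.Generator,
    n_nodes: int,
    alphabet=("A", "B", "C"),
    positions=(2, 3, 4, 6),
    anomers=("a", "b"),
) -> GlycanTree:
    """Random rooted labeled tree by random attachment."""
    nodes = {1: Monosaccharide(str(rng.choice(alphabet)), str(rng.choice(anomers)))}
    edges = []
    for i in range(2, n_nodes + 1):
        parent = int(rng.integers(1, i))
        nodes[i] = Monosaccharide(str(rng.choice(alphabet)), str(rng.choice(anomers)))
        edges.append((parent, i, Linkage(int(rng.choice(positions)), 1)))
    return GlycanTree(nodes, edges)


def permute_children(rng: np.random.Generator, tree: GlycanTree) -> GlycanTree:
    """Isomorphic copy with shuffled node ids and child order."""
    ids = list(tree.nodes)
    perm = list(rng.permutation(ids))
    relabel = dict(zip(ids, perm))
    nodes = {relabel[i]: m for i, m in tree.nodes.items()}
    edges = [(relabel[p], relabel[c], lk) for p, c, lk in tree.edges]
    rng.shuffle(edges)
    return GlycanTree(nodes, edges)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


# ---------------------------------------------------------------------------
# oracle: rooted isomorphism by permutation backtracking


def trees_isomorphic(t1: GlycanTree, t2: GlycanTree) -> bool:
    if len(t1) != len(t2):
        return False

    def iso(n1: int, n2: int) -> bool:
        if t1.nodes[n1] != t2.nodes[n2]:
            return False
        c1, c2 = t1.children(n1), t2.children(n2)
        if len(c1) != len(c2):
            return False
        for perm in itertools.permutations(range(len(c2))):
            ok = True
            for i, (child1, lk1) in enumerate(c1):
                child2, lk2 = c2[perm[i]]
                if lk1 != lk2 or not iso(child1, child2):
                    ok = False
                    break
            if ok:
                return True
        return not c1

    return iso(t1.root, t2.root)


# ---------------------------------------------------------------------------
# oracle: connected-subtree enumeration by node-subset scan


def brute_force_subtrees(tree: GlycanTree) -> list[GlycanTree]:
    """All connected subtrees, deduplicated by the isomorphism oracle."""
    reps: list[GlycanTree] = []
    node_ids = list(tree.nodes)
    for r in range(1, len(node_ids) + 1):
        for subset in itertools.combinations(node_ids, r):
            s = set(subset)
            edges = [e for e in tree.edges if e[0] in s and e[1] in s]
            if len(edges) != len(s) - 1:  # induced forest, not connected
                continue
            sub = GlycanTree({i: tree.nodes[i] for i in s}, edges)
            if not any(trees_isomorphic(sub, t) for t in reps):
                reps.append(sub)
    return reps


# ---------------------------------------------------------------------------
# oracle: embedding count by exhaustive injective assignment


def brute_force_embedding_count(glycan: GlycanTree, pattern: GlycanTree) -> int:
    """Anchor positions where the pattern embeds, counted naively."""

    def mono_ok(gm, pm):
        return gm.symbol == pm.symbol and (pm.anomer == "x" or gm.anomer == pm.anomer)

    def link_ok(glk, plk):
        return (plk.parent_pos is None or glk.parent_pos == plk.parent_pos) and (
            plk.child_pos is None or glk.child_pos == plk.child_pos
        )

    def embeds(gn: int, pn: int) -> bool:
        if not mono_ok(glycan.nodes[gn], pattern.nodes[pn]):
            return False
        pk = pattern.children(pn)
        gk = glycan.children(gn)
        if len(pk) > len(gk):
            return False
        for chosen in itertools.permutations(range(len(gk)), len(pk)):
            if all(
                link_ok(gk[gi][1], plk) and embeds(gk[gi][0], pc)
                for gi, (pc, plk) in zip(chosen, pk)
            ):
                return True
        return not pk or False

    return sum(1 for gn in glycan.nodes if embeds(gn, pattern.root))


# ---------------------------------------------------------------------------
# small shared structures


def chain(symbols: str, pos: int = 3, anomer: str = "b") -> GlycanTree:
    """Linear chain A-B-C... with identical linkages."""
    nodes = {i + 1: Monosaccharide(s, anomer) for i, s in enumerate(symbols)}
    edges = [
        (i + 1, i + 2, Linkage(pos, 1)) for i in range(len(symbols) - 1)
    ]
    return GlycanTree(nodes, edges)


@pytest.fixture
def linear_abc():
    return chain("ABC")
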