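"""Substructure enumeration, matching, and substructure abundance profiles.

A glycan substructure is any connected subtree of a glycan, rooted at its
node nearest the reducing end.  Every glycan in a dataset is decomposed
exhaustively (all connected subtrees, i.e. every structure obtainable by
breaking one linkage or any combination of linkages), the union is
deduplicated by canonical key into a substructure set S, and each sample's
substructure abundance vector is

    P_i(s) = sum_j  x_sj * g_ij / sum_j g_ij

where x_sj is 1 iff substructure s occurs in glycan j (binary presence, not
the embedding count) and g_ij are the measured abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import pandas as pd

from .glycan_io import GlycanIOError, GlycanTree, Glycoprofile, Linkage

__all__ = [
    "SubstructureSet",
    "SubstructureProfile",
    "enumerate_substructures",
    "contains",
    "match_anchored",
    "build_substructure_set",
    "presence_matrix",
    "substructure_profile",
]


# ---------------------------------------------------------------------------
# matching

def _mono_matches(glycan_m, pattern_m) -> bool:
    if glycan_m.symbol != pattern_m.symbol:
        return False
    if pattern_m.anomer == "x":
        return True
    return glycan_m.anomer == pattern_m.anomer


def _pos_matches(glycan_pos: int | None, pattern_pos: int | None) -> bool:
    if pattern_pos is None:
        return True
    return glycan_pos == pattern_pos


def _linkage_matches(glycan_lk: Linkage, pattern_lk: Linkage) -> bool:
    return _pos_matches(glycan_lk.parent_pos, pattern_lk.parent_pos) and _pos_matches(
        glycan_lk.child_pos, pattern_lk.child_pos
    )


def match_anchored(
    glycan: GlycanTree,
    pattern: GlycanTree,
    gnode: int | None = None,
    pnode: int | None = None,
    _memo: dict | None = None,
) -> bool:
    """Does ``pattern`` embed in ``glycan`` with its root mapped to ``gnode``?

    Pattern-side unknowns (anomer ``x``, linkage position ``None``) act as
    wildcards; glycan-side unknowns match only a pattern-side unknown.
    Children are matched injectively.
    """
    gnode = glycan.root if gnode is None else gnode
    pnode = pattern.root if pnode is None else pnode
    memo = {} if _memo is None else _memo
    key = (gnode, pnode)
    if key in memo:
        return memo[key]
    ok = _match_node(glycan, pattern, gnode, pnode, memo)
    memo[key] = ok
    return ok


def _match_node(glycan, pattern, gnode, pnode, memo) -> bool:
    if not _mono_matches(glycan.nodes[gnode], pattern.nodes[pnode]):
        return False
    pkids = pattern.children(pnode)
    if not pkids:
        return True
    gkids = glycan.children(gnode)
    if len(pkids) > len(gkids):
        return False
    # injective assignment of pattern children to glycan children (backtracking;
    # branching factors in glycans are tiny)
    compat = []
    for pc, plk in pkids:
        slots = [
            i
            for i, (gc, glk) in enumerate(gkids)
            if _linkage_matches(glk, plk)
            and match_anchored(glycan, pattern, gc, pc, memo)
        ]
        if not slots:
            return False
        compat.append(slots)

    used: set[int] = set()

    def assign(i: int) -> bool:
        if i == len(compat):
            return True
        for slot in compat[i]:
            if slot not in used:
                used.add(slot)
                if assign(i + 1):
                    used.discard(slot)
                    return True
                used.discard(slot)
        return False

    return assign(0)


def contains(glycan: GlycanTree, substructure: GlycanTree) -> int:
    """Number of anchor nodes of ``glycan`` at which ``substructure`` embeds."""
    if len(substructure) > len(glycan):
        return 0
    memo: dict = {}
    return sum(
        1
        for gnode in glycan.nodes
        if match_anchored(glycan, substructure, gnode, substructure.root, memo)
    )


# ---------------------------------------------------------------------------
# enumeration


def _extract(tree: GlycanTree, nodeset: frozenset[int]) -> GlycanTree:
    nodes = {i: tree.nodes[i] for i in nodeset}
    edges = [(p, c, lk) for p, c, lk in tree.edges if p in nodeset and c in nodeset]
    return GlycanTree(nodes, edges)


def _rooted_node_sets(tree: GlycanTree, node: int) -> list[frozenset[int]]:
    """All node sets of connected subtrees rooted at ``node``."""
    child_options: list[list[frozenset[int] | None]] = []
    for child, _ in tree.children(node):
        opts: list[frozenset[int] | None] = [None]
        opts.extend(_rooted_node_sets(tree, child))
        child_options.append(opts)
    out = []
    for combo in product(*child_options):
        s = {node}
        for part in combo:
            if part is not None:
                s |= part
        out.append(frozenset(s))
    return out


@dataclass
class SubstructureSet:
    """Ordered, deduplicated set of canonical substructure trees.

    Members are ordered by monosaccharide count, ties broken by canonical
    key, so the order is stable across runs.
    """

    members: dict[str, GlycanTree] = field(default_factory=dict)

    def add(self, tree: GlycanTree) -> None:
        self.members.setdefault(tree.key, tree)

    def update(self, other: "SubstructureSet") -> None:
        for t in other.members.values():
            self.add(t)

    def sorted(self) -> "SubstructureSet":
        ordered = dict(
            sorted(self.members.items(), key=lambda kv: (len(kv[1]), kv[0]))
        )
        return SubstructureSet(ordered)

    def keys(self) -> list[str]:
        return list(self.members.keys())

    def __iter__(self):
        return iter(self.members.values())

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, key: str) -> bool:
        return key in self.members

    def __getitem__(self, key: str) -> GlycanTree:
        return self.members[key]


def enumerate_substructures(
    tree: GlycanTree, root_constraint: GlycanTree | None = None
) -> SubstructureSet:
    """Every connected subtree of ``tree``, deduplicated by canonical key.

    With ``root_constraint`` (e.g. the N-glycan core, lactose, or a single
    monosaccharide), only subtrees whose reducing-end side contains the
    constraint anchored at their root are kept.
    """
    out = SubstructureSet()
    for node in tree.nodes:
        for nodeset in _rooted_node_sets(tree, node):
            sub = _extract(tree, nodeset)
            if root_constraint is not None and not match_anchored(
                sub, root_constraint
            ):
                continue
            out.add(sub)
    return out.sorted()


def build_substructure_set(
    profiles: list[Glycoprofile], root_constraint: GlycanTree | None = None
) -> SubstructureSet:
    """Union of all glycans' substructures over all profiles, sorted."""
    if not profiles:
        raise GlycanIOError("no profiles given")
    out = SubstructureSet()
    seen: set[str] = set()
    for prof in profiles:
        for tree in prof.glycans():
            if tree.key in seen:
                continue
            seen.add(tree.key)
            out.update(enumerate_substructures(tree, root_constraint))
    return out.sorted()


# ---------------------------------------------------------------------------
# profiles


def presence_matrix(
    glycans: list[GlycanTree], S: SubstructureSet
) -> pd.DataFrame:
    """Binary glycan x substructure presence matrix (1 iff >= 1 embedding)."""
    data = {}
    for skey, stree in S.members.items():
        data[skey] = [1 if contains(g, stree) > 0 else 0 for g in glycans]
    return pd.DataFrame(data, index=[g.key for g in glycans], dtype=int)


@dataclass
class SubstructureProfile:
    """Per-sample abundance over a substructure set.

    Values never exceed 1 and are monotone under containment: a substructure
    is at least as abundant as any larger substructure containing it.
    """

    sample_id: str
    values: dict[str, float]

    def series(self) -> pd.Series:
        return pd.Series(self.values, name=self.sample_id)

    def __getitem__(self, key: str) -> float:
        return self.values[key]


def substructure_profile(
    profile: Glycoprofile, S: SubstructureSet, _presence: pd.DataFrame | None = None
) -> SubstructureProfile:
    """Transform one glycoprofile into its substructure abundance vector."""
    values = {skey: 0.0 for skey in S.members}
    for gkey, abundance in profile.abundances.items():
        gtree = profile.structures[gkey]
        if _presence is not None and gkey in _presence.index:
            row = _presence.loc[gkey]
            for skey in S.members:
                if row[skey]:
                    values[skey] += abundance
        else:
            for skey, stree in S.members.items():
                if contains(gtree, stree) > 0:
                    values[skey] += abundance
    return SubstructureProfile(profile.sample_id, values)


def substructure_profiles(
    profiles: list[Glycoprofile], S: SubstructureSet
) -> list[SubstructureProfile]:
    """Vectorized convenience: decompose many profiles against one set."""
    all_glycans: dict[str, GlycanTree] = {}
    for p in profiles:
        all_glycans.update(p.structures)
    pres = presence_matrix(list(all_glycans.values()), S)
    return [substructure_profile(p, S, _presence=pres) for p in profiles]
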