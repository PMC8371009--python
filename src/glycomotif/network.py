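"""Biosynthetic substructure networks and glyco-motif selection.

The substructure network is a DAG over the substructure set: each node is a
substructure at a level equal to its monosaccharide count, and an edge
connects a parent to a child that contains it and has exactly one more
monosaccharide (one biosynthetic step).  Edges can be annotated with the
glycosyltransferase family catalyzing the addition.

Glyco-motif selection prunes the network losslessly: a parent whose
abundance equals some child's in every sample carries no extra information
(the added monosaccharide is unperturbed across samples) and is merged into
that child.  Node weights, initialized at 1, are redistributed root-to-leaf
— a pruned node's weight is divided equally among the children it matched —
so that total weight is conserved and divergent descendants accumulate
weight.  The surviving nodes are the glyco-motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import yaml

from .glycan_io import (
    GlycanIOError,
    GlycanTree,
    Glycoprofile,
    Linkage,
    Monosaccharide,
    parse_glycoct,
)
from .substructure import (
    SubstructureProfile,
    SubstructureSet,
    contains,
    match_anchored,
)

__all__ = [
    "SubstructureNetwork",
    "EnzymeRule",
    "MotifProfile",
    "NetworkError",
    "build_network",
    "annotate_enzymes",
    "select_glyco_motifs",
    "motif_profile",
    "reconstruct_profile",
    "coverage_fraction",
    "sample_occurrence",
    "load_enzyme_rules",
    "default_enzyme_rules",
    "UNANNOTATED",
]

UNANNOTATED = "unannotated"


class NetworkError(ValueError):
    """Structural problem in the substructure network."""


@dataclass
class SubstructureNetwork:
    """DAG over canonical substructure keys.

    Node attributes: ``tree`` (GlycanTree), ``level`` (monosaccharide
    count), ``weight`` (>= 0), ``motif`` (bool).  Edge attribute:
    ``enzyme``.  ``merge_trace`` records, for every pruned node, the
    children that absorbed its weight (audit trail for reconstruction).
    """

    graph: nx.DiGraph
    root_level: int
    merge_trace: dict[str, list[str]] = field(default_factory=dict)

    def tree(self, key: str) -> GlycanTree:
        return self.graph.nodes[key]["tree"]

    def level(self, key: str) -> int:
        return self.graph.nodes[key]["level"]

    def weight(self, key: str) -> float:
        return self.graph.nodes[key]["weight"]

    def is_motif(self, key: str) -> bool:
        return self.graph.nodes[key]["motif"]

    def motif_keys(self) -> list[str]:
        return [k for k in self.topological_keys() if self.is_motif(k)]

    def topological_keys(self) -> list[str]:
        return sorted(self.graph.nodes, key=lambda k: (self.level(k), k))

    def total_weight(self) -> float:
        return float(sum(d["weight"] for _, d in self.graph.nodes(data=True)))

    def to_graphml(self, path) -> None:
        g = nx.DiGraph()
        for k, d in self.graph.nodes(data=True):
            g.add_node(k, level=d["level"], weight=float(d["weight"]),
                       motif=bool(d["motif"]))
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(u, v, enzyme=d.get("enzyme", UNANNOTATED))
        nx.write_graphml(g, path)


def build_network(S: SubstructureSet, core: GlycanTree | None = None) -> SubstructureNetwork:
    """Connect substructures differing by exactly one monosaccharide.

    An edge (p, c) exists iff ``c`` contains ``p`` and level(c) = level(p)+1.
    Roots sit at the core level (or the monosaccharide level when no core is
    given); any deeper node without a parent violates closure and is an
    error.
    """
    if len(S) == 0:
        raise NetworkError("empty substructure set")
    g = nx.DiGraph()
    by_level: dict[int, list[str]] = {}
    for key, tree in S.members.items():
        lvl = len(tree)
        g.add_node(key, tree=tree, level=lvl, weight=1.0, motif=True)
        by_level.setdefault(lvl, []).append(key)
    for lvl in sorted(by_level):
        for pkey in by_level[lvl]:
            ptree = S[pkey]
            for ckey in by_level.get(lvl + 1, ()):
                if contains(S[ckey], ptree) > 0:
                    g.add_edge(pkey, ckey)
    root_level = len(core) if core is not None else min(by_level)
    for key in g.nodes:
        if g.nodes[key]["level"] > root_level and g.in_degree(key) == 0:
            raise NetworkError(
                f"closure violation: node at level {g.nodes[key]['level']} has "
                f"no path to a root ({key})"
            )
    return SubstructureNetwork(g, root_level)


# ---------------------------------------------------------------------------
# enzyme annotation


@dataclass(frozen=True)
class EnzymeRule:
    """One glycosyltransferase rule: which residue is added, via which
    linkage, onto which acceptor context.

    ``context`` is a small tree pattern that must match anchored at the
    acceptor residue; ``None`` positions/anomers act as wildcards.
    """

    enzyme: str
    residue: str
    anomer: str = "x"  # of the added residue; 'x' = wildcard
    parent_pos: int | None = None
    child_pos: int | None = None
    context: GlycanTree | None = None

    def matches(self, residue: Monosaccharide, linkage: Linkage,
                child_tree: GlycanTree, acceptor: int) -> bool:
        if residue.symbol != self.residue:
            return False
        if self.anomer != "x" and residue.anomer != self.anomer:
            return False
        if self.parent_pos is not None and linkage.parent_pos != self.parent_pos:
            return False
        if self.child_pos is not None and linkage.child_pos != self.child_pos:
            return False
        if self.context is not None:
            return match_anchored(child_tree, self.context, gnode=acceptor)
        return True


def _reaction_of_edge(ptree: GlycanTree, ctree: GlycanTree):
    """Identify the residue addition turning parent into child.

    Deletes each leaf of the child in canonical order and returns the first
    deletion whose remainder is isomorphic to the parent: (added residue,
    linkage, acceptor node id in child).
    """
    parent_of = {c: (p, lk) for p, c, lk in ctree.edges}
    leaves = sorted(
        (n for n in ctree.nodes if not ctree.children(n) and n in parent_of),
        key=lambda n: (ctree.nodes[n].symbol, ctree.nodes[n].anomer, n),
    )
    for leaf in leaves:
        nodes = {i: m for i, m in ctree.nodes.items() if i != leaf}
        edges = [(p, c, lk) for p, c, lk in ctree.edges if c != leaf]
        if GlycanTree(nodes, edges).key == ptree.key:
            acc, lk = parent_of[leaf]
            return ctree.nodes[leaf], lk, acc
    raise NetworkError(
        "edge does not correspond to a single-residue addition: "
        f"{ptree.key!r} -> {ctree.key!r}"
    )


def annotate_enzymes(
    network: SubstructureNetwork, rules: list[EnzymeRule]
) -> SubstructureNetwork:
    """Label each edge with the enzyme rule matching its residue addition.

    Edges covered by no rule carry the ``unannotated`` token; an edge matched
    by two rules with different enzyme labels is a rule-set ambiguity error.
    """
    g = network.graph
    for u, v in g.edges:
        residue, lk, acc = _reaction_of_edge(network.tree(u), network.tree(v))
        hits = [r for r in rules if r.matches(residue, lk, network.tree(v), acc)]
        labels = sorted({r.enzyme for r in hits})
        if len(labels) > 1:
            raise NetworkError(
                f"ambiguous enzyme rules for edge adding {residue.symbol} "
                f"{lk.token()}: {labels}"
            )
        g.edges[u, v]["enzyme"] = labels[0] if labels else UNANNOTATED
    return network


def _parse_context(spec) -> GlycanTree | None:
    if spec in (None, "", "any"):
        return None
    if isinstance(spec, str) and "RES" in spec:
        return parse_glycoct(spec)
    # bare symbol: single-residue pattern with unknown anomer
    return GlycanTree({1: Monosaccharide(str(spec), "x")}, [])


def load_enzyme_rules(source) -> list[EnzymeRule]:
    """Load rules from YAML text/path: a list of mappings with keys
    enzyme, residue, anomer, parent_pos, child_pos, context."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "\n" not in text and not text.lstrip().startswith("-"):
            with open(text) as fh:
                text = fh.read()
    raw = yaml.safe_load(text)
    rules = []
    for entry in raw:
        rules.append(
            EnzymeRule(
                enzyme=str(entry["enzyme"]),
                residue=str(entry["residue"]),
                anomer=str(entry.get("anomer", "x")),
                parent_pos=entry.get("parent_pos"),
                child_pos=entry.get("child_pos"),
                context=_parse_context(entry.get("context")),
            )
        )
    return rules


_NGLYCAN_RULES_YAML = """
- {enzyme: MgatT,   residue: GlcNAc, anomer: b, parent_pos: 2, child_pos: 1, context: Man}
- {enzyme: MgatT,   residue: GlcNAc, anomer: b, parent_pos: 4, child_pos: 1, context: Man}
- {enzyme: MgatT,   residue: GlcNAc, anomer: b, parent_pos: 6, child_pos: 1, context: Man}
- {enzyme: iGnT,    residue: GlcNAc, anomer: b, parent_pos: 3, child_pos: 1, context: Gal}
- {enzyme: B4galT,  residue: Gal,    anomer: b, parent_pos: 4, child_pos: 1, context: GlcNAc}
- {enzyme: a3SiaT,  residue: Neu5Ac, anomer: a, parent_pos: 3, child_pos: 2, context: Gal}
- {enzyme: a6SiaT,  residue: Neu5Ac, anomer: a, parent_pos: 6, child_pos: 2, context: Gal}
- {enzyme: Fut,     residue: Fuc,    anomer: a, parent_pos: 6, child_pos: 1, context: GlcNAc}
- {enzyme: Fut,     residue: Fuc,    anomer: a, parent_pos: 3, child_pos: 1, context: GlcNAc}
"""

_HMO_RULES_YAML = """
- {enzyme: b3GnT,   residue: GlcNAc, anomer: b, parent_pos: 3, child_pos: 1, context: Gal}
- {enzyme: b6GnT,   residue: GlcNAc, anomer: b, parent_pos: 6, child_pos: 1, context: Gal}
- {enzyme: b3GalT,  residue: Gal,    anomer: b, parent_pos: 3, child_pos: 1, context: GlcNAc}
- {enzyme: b4GalT,  residue: Gal,    anomer: b, parent_pos: 4, child_pos: 1, context: GlcNAc}
- {enzyme: FUT2,    residue: Fuc,    anomer: a, parent_pos: 2, child_pos: 1, context: Gal}
- {enzyme: FUT3,    residue: Fuc,    anomer: a, parent_pos: 4, child_pos: 1, context: GlcNAc}
- {enzyme: ST3GalT, residue: Neu5Ac, anomer: a, parent_pos: 3, child_pos: 2, context: Gal}
- {enzyme: ST6GalT, residue: Neu5Ac, anomer: a, parent_pos: 6, child_pos: 2, context: Gal}
- {enzyme: ST6GnT,  residue: Neu5Ac, anomer: a, parent_pos: 6, child_pos: 2, context: GlcNAc}
"""


def default_enzyme_rules(kind: str) -> list[EnzymeRule]:
    """Shipped rule sets: ``nglycan`` (Mgat/B4galT/iGnT/SiaT/Fut families) or
    ``hmo`` (milk-oligosaccharide transferases)."""
    if kind == "nglycan":
        return load_enzyme_rules(_NGLYCAN_RULES_YAML)
    if kind == "hmo":
        return load_enzyme_rules(_HMO_RULES_YAML)
    raise ValueError(f"unknown rule set {kind!r}")


# ---------------------------------------------------------------------------
# glyco-motif selection


def select_glyco_motifs(
    network: SubstructureNetwork,
    profiles: list[SubstructureProfile],
    tol: float = 1e-9,
) -> SubstructureNetwork:
    """Prune redundant parents, redistributing their weight to the matching
    children; surviving nodes are flagged as glyco-motifs.

    A parent is redundant when its abundance vector across *all* profiles
    equals some child's within relative tolerance ``tol``.  Processing is
    topological (root to leaf) so weight flows toward divergent descendants;
    total weight is conserved.
    """
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    g = network.graph
    vec = {
        key: np.array([p.values[key] for p in profiles], dtype=float)
        for key in g.nodes
    }
    for key in g.nodes:
        g.nodes[key]["weight"] = 1.0
        g.nodes[key]["motif"] = True
    network.merge_trace.clear()
    for pkey in network.topological_keys():
        matching = [
            ckey
            for ckey in sorted(g.successors(pkey))
            if np.allclose(vec[pkey], vec[ckey], rtol=tol, atol=tol)
        ]
        if not matching:
            continue
        share = g.nodes[pkey]["weight"] / len(matching)
        for ckey in matching:
            g.nodes[ckey]["weight"] += share
        g.nodes[pkey]["weight"] = 0.0
        g.nodes[pkey]["motif"] = False
        network.merge_trace[pkey] = matching
    return network


@dataclass
class MotifProfile:
    """Restriction of a substructure profile to the selected glyco-motifs."""

    sample_id: str
    values: dict[str, float]

    def series(self):
        import pandas as pd

        return pd.Series(self.values, name=self.sample_id)


def motif_profile(
    profile: SubstructureProfile, network: SubstructureNetwork
) -> MotifProfile:
    return MotifProfile(
        profile.sample_id,
        {k: profile.values[k] for k in network.motif_keys()},
    )


def reconstruct_profile(
    motifs: MotifProfile, network: SubstructureNetwork
) -> SubstructureProfile:
    """Invert motif restriction: recover every pruned node's abundance from
    the retained descendant it was merged into (the lossless-pruning claim)."""
    resolved: dict[str, float] = dict(motifs.values)

    def value_of(key: str) -> float:
        if key in resolved:
            return resolved[key]
        if key not in network.merge_trace:
            raise NetworkError(f"pruned node {key!r} has no merge trace")
        v = value_of(network.merge_trace[key][0])
        resolved[key] = v
        return v

    full = {key: value_of(key) for key in network.graph.nodes}
    return SubstructureProfile(motifs.sample_id, full)


# ---------------------------------------------------------------------------
# coverage and occurrence


def _nonzero_keys(profile) -> set[str]:
    if isinstance(profile, Glycoprofile):
        return {k for k, v in profile.abundances.items() if v > 0}
    return {k for k, v in profile.values.items() if v > 0}


def coverage_fraction(profile, pan_network: SubstructureNetwork) -> float:
    """Fraction of pan-network nodes represented in one sample.

    For a glycoprofile a node counts when it equals a measured glycan; for
    substructure/motif profiles a node counts when its abundance is nonzero.
    """
    n = pan_network.graph.number_of_nodes()
    if n == 0:
        raise NetworkError("empty network")
    keys = _nonzero_keys(profile)
    return sum(1 for k in pan_network.graph.nodes if k in keys) / n


def sample_occurrence(profiles) -> "dict[str, float]":
    """Per-structure proportion of samples with nonzero abundance."""
    if not profiles:
        raise ValueError("no profiles")
    sets = [_nonzero_keys(p) for p in profiles]
    universe = sorted(set().union(*sets) if sets else set())
    n = len(profiles)
    return {k: sum(1 for s in sets if k in s) / n for k in universe}
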