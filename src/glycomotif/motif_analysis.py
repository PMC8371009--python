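"""Clustering of glycoprofiles and motifs, representative substructures,
and differential abundance against a reference sample.

Profiles (or motifs) are clustered hierarchically with complete linkage on
correlation distance (1 - Pearson r), cut either at a fixed distance
threshold (0.5 by default) or at an elbow-selected number of clusters.
Each motif cluster is summarized by a representative substructure: member
trees are superimposed by anchored alignment from the shared root, each
monosaccharide position accumulates the weight of the members containing
it, and positions above a 51% weighted-frequency threshold are retained.
Per-sample cluster abundances (weighted means over members) are centered on
a reference sample (e.g. wild type), scaled by the standard deviation, and
tested with a one-sided one-sample Wilcoxon signed-rank test; the effect
size is r = z / sqrt(N) and significance is Bonferroni-corrected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats

from .glycan_io import GlycanTree, Linkage, Monosaccharide
from .network import SubstructureNetwork, UNANNOTATED

__all__ = [
    "ClusterAssignment",
    "RepresentativeSubstructure",
    "DifferentialResult",
    "cluster",
    "correlation_distance_matrix",
    "representative_substructure",
    "cluster_abundance",
    "zscore_vs_reference",
    "differential_test",
    "collapse_network_by_clusters",
]


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusterAssignment:
    items: list[str]
    labels: list[int]
    cut: float | str
    method: str = "complete"
    metric: str = "correlation"
    degenerate_items: list[str] = field(default_factory=list)

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for item, lab in zip(self.items, self.labels):
            out.setdefault(lab, []).append(item)
        return out

    def n_clusters(self) -> int:
        return len(set(self.labels))


def correlation_distance_matrix(values: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Pairwise 1 - Pearson r over rows.

    Zero-variance rows have undefined correlation; their distance to every
    other item is defined as 1 (uninformative) and they are reported back so
    callers can flag them.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    sd = values.std(axis=1)
    degenerate = [i for i in range(n) if sd[i] == 0]
    dist = np.ones((n, n))
    np.fill_diagonal(dist, 0.0)
    ok = [i for i in range(n) if sd[i] > 0]
    if len(ok) >= 2:
        sub = values[ok]
        r = np.corrcoef(sub)
        d = 1.0 - r
        for a, i in enumerate(ok):
            for b, j in enumerate(ok):
                dist[i, j] = d[a, b]
    np.fill_diagonal(dist, 0.0)
    return dist, degenerate


def _elbow_k(linkage_matrix: np.ndarray, dist: np.ndarray, n: int) -> int:
    """k at the maximum second difference of within-cluster sum of distances
    over k = 1..min(10, n-1)."""
    kmax = min(10, n - 1)
    wss = []
    ks = list(range(1, kmax + 1))
    for k in ks:
        labels = sch.fcluster(linkage_matrix, t=k, criterion="maxclust")
        total = 0.0
        for lab in set(labels):
            idx = np.where(labels == lab)[0]
            if len(idx) > 1:
                total += dist[np.ix_(idx, idx)].sum() / 2.0
        wss.append(total)
    if len(ks) < 3:
        return ks[-1]
    second = [wss[i - 1] - 2 * wss[i] + wss[i + 1] for i in range(1, len(ks) - 1)]
    return ks[1 + int(np.argmax(second))]


def cluster(
    matrix: pd.DataFrame,
    axis: str = "rows",
    cut: float | str = 0.5,
) -> ClusterAssignment:
    """Complete-linkage hierarchical clustering on correlation distance.

    ``matrix`` is items x features when ``axis='rows'`` (transposed
    otherwise).  ``cut`` is a distance threshold (default 0.5) or the string
    ``'elbow'`` to pick k by the elbow rule on within-cluster distance sums.
    """
    if axis == "columns":
        matrix = matrix.T
    items = [str(i) for i in matrix.index]
    values = matrix.to_numpy(dtype=float)
    if len(items) < 2:
        raise ValueError("need at least two items to cluster")
    if not np.isfinite(values).all():
        raise ValueError("non-finite values in clustering matrix")
    dist, degenerate_idx = correlation_distance_matrix(values)
    condensed = dist[np.triu_indices(len(items), k=1)]
    # guard tiny negative rounding from 1 - r
    condensed = np.clip(condensed, 0.0, None)
    Z = sch.linkage(condensed, method="complete")
    if cut == "elbow":
        k = _elbow_k(Z, dist, len(items))
        labels = sch.fcluster(Z, t=k, criterion="maxclust")
    else:
        labels = sch.fcluster(Z, t=float(cut), criterion="distance")
    return ClusterAssignment(
        items=items,
        labels=[int(x) for x in labels],
        cut=cut,
        degenerate_items=[items[i] for i in degenerate_idx],
    )


# ---------------------------------------------------------------------------
# representative substructures


@dataclass
class RepresentativeSubstructure:
    cluster_id: int | str
    consensus: GlycanTree | None
    position_fractions: dict[int, float]  # node id in consensus -> fraction


class _UnionNode:
    __slots__ = ("mono", "link", "weight", "children")

    def __init__(self, mono: Monosaccharide, link: Linkage | None):
        self.mono = mono
        self.link = link
        self.weight = 0.0
        self.children: list[_UnionNode] = []


def _merge_member(unode: _UnionNode, tree: GlycanTree, node: int, w: float) -> None:
    unode.weight += w
    kids = sorted(
        tree.children(node),
        key=lambda cl: (
            tree.nodes[cl[0]].symbol,
            tree.nodes[cl[0]].anomer,
            -1 if cl[1].parent_pos is None else cl[1].parent_pos,
        ),
    )
    used: set[int] = set()
    for child, lk in kids:
        cm = tree.nodes[child]
        slot = None
        for i, uc in enumerate(unode.children):
            if i in used:
                continue
            if uc.mono == cm and uc.link == lk:
                slot = i
                break
        if slot is None:
            unode.children.append(_UnionNode(cm, lk))
            slot = len(unode.children) - 1
        used.add(slot)
        _merge_member(unode.children[slot], tree, child, w)


def representative_substructure(
    members: list[GlycanTree],
    weights: list[float],
    threshold: float = 0.51,
    cluster_id: int | str = 0,
) -> RepresentativeSubstructure:
    """Weighted consensus tree of a motif cluster.

    Members are superimposed by anchored alignment from the shared root;
    each position's fraction is the weight share of members containing it;
    positions with fraction > ``threshold`` are retained, restricted to the
    connected component containing the root.
    """
    if not members:
        raise ValueError("empty cluster")
    if len(weights) != len(members):
        raise ValueError("weights and members differ in length")
    if any(w <= 0 for w in weights):
        raise ValueError("weights must be positive")
    roots = {
        (t.nodes[t.root].symbol, t.nodes[t.root].anomer) for t in members
    }
    if len(roots) > 1:
        raise ValueError(f"members have incompatible roots: {sorted(roots)}")
    total = float(sum(weights))
    root_mono = members[0].nodes[members[0].root]
    union = _UnionNode(Monosaccharide(root_mono.symbol, root_mono.anomer), None)
    for tree, w in zip(members, weights):
        _merge_member(union, tree, tree.root, w / total)

    # collect retained positions top-down (connectivity through the root)
    nodes: dict[int, Monosaccharide] = {}
    edges: list[tuple[int, int, Linkage]] = []
    fractions: dict[int, float] = {}
    counter = [0]

    def build(unode: _UnionNode, parent_id: int | None) -> None:
        if unode.weight <= threshold and parent_id is not None:
            return
        if parent_id is None and unode.weight <= threshold:
            return
        counter[0] += 1
        nid = counter[0]
        nodes[nid] = unode.mono
        fractions[nid] = unode.weight
        if parent_id is not None:
            edges.append((parent_id, nid, unode.link))
        for uc in unode.children:
            build(uc, nid)

    build(union, None)
    consensus = GlycanTree(nodes, edges) if nodes else None
    return RepresentativeSubstructure(cluster_id, consensus, fractions)


# ---------------------------------------------------------------------------
# abundance summaries and differential testing


def cluster_abundance(
    member_keys: list[str],
    member_weights: list[float],
    profiles,
) -> pd.Series:
    """Weighted mean abundance of cluster members, per sample."""
    if not member_keys:
        raise ValueError("empty cluster")
    w = np.asarray(member_weights, dtype=float)
    out = {}
    for p in profiles:
        vals = np.array([p.values[k] for k in member_keys], dtype=float)
        out[p.sample_id] = float(np.average(vals, weights=w)) if w.sum() > 0 else 0.0
    return pd.Series(out)


def zscore_vs_reference(values: pd.Series, reference: str) -> tuple[pd.Series, bool]:
    """Center on the reference sample and scale by the across-sample sd.

    Returns the scaled series and a degenerate-scale flag (True when the sd
    is zero, in which case all values map to 0).
    """
    if reference not in values.index:
        raise KeyError(f"reference sample {reference!r} not present")
    if len(values) < 2:
        raise ValueError("need at least two samples")
    sd = float(values.std(ddof=1))
    if sd == 0 or not math.isfinite(sd):
        warnings.warn("degenerate scale: zero variance across samples")
        return pd.Series(0.0, index=values.index), True
    return (values - values[reference]) / sd, False


@dataclass
class DifferentialResult:
    item_id: str
    sample_id: str
    statistic: float
    z: float
    p: float
    effect_size_r: float
    significant: bool
    alpha: float
    n_tests: int


def _signed_rank_z(diffs: np.ndarray, alternative: str) -> tuple[float, float]:
    """Normal-approximation z (with continuity and tie correction) for the
    one-sample Wilcoxon signed-rank statistic; returns (W+, z)."""
    d = diffs[diffs != 0]
    n = len(d)
    if n == 0:
        return 0.0, 0.0
    ranks = scipy.stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / 48.0
    sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    if sigma == 0:
        return w_plus, 0.0
    # continuity correction toward the null mean
    if alternative == "greater":
        z = (w_plus - mu - 0.5) / sigma
    else:
        z = (w_plus - mu + 0.5) / sigma
    return w_plus, z


def differential_test(
    member_values: np.ndarray,
    reference_values: np.ndarray,
    alternative: str = "greater",
    n_tests: int = 1,
    alpha: float = 0.05,
    item_id: str = "",
    sample_id: str = "",
) -> DifferentialResult:
    """One-sided one-sample Wilcoxon signed-rank test of a sample's cluster
    member abundances against the reference sample's.

    Exact p-values for N <= 25 zero-free differences, normal approximation
    with continuity correction above; the approximation's z supplies the
    effect size r = |z| / sqrt(N) in both regimes.  Bonferroni correction:
    significant iff p < alpha / n_tests.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    diffs = np.asarray(member_values, dtype=float) - np.asarray(
        reference_values, dtype=float
    )
    n_total = len(diffs)
    if n_total < 5:
        raise ValueError("need at least 5 member values for a signed-rank test")
    nz = diffs[diffs != 0]
    if len(nz) == 0:
        return DifferentialResult(
            item_id, sample_id, 0.0, 0.0, 1.0, 0.0, False, alpha, n_tests
        )
    mode = "exact" if len(nz) <= 25 else "approx"
    res = scipy.stats.wilcoxon(
        nz, alternative=alternative, method=mode, correction=True
    )
    w_plus, z = _signed_rank_z(diffs, alternative)
    r = min(abs(z) / math.sqrt(n_total), 1.0)
    p = float(res.pvalue)
    return DifferentialResult(
        item_id,
        sample_id,
        w_plus,
        z,
        p,
        r,
        p < alpha / n_tests,
        alpha,
        n_tests,
    )


def bonferroni_criterion(alpha: float, n_tests: int) -> float:
    """Per-test significance criterion under Bonferroni correction."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# simplified (cluster-collapsed) network


def collapse_network_by_clusters(
    network: SubstructureNetwork, clusters: ClusterAssignment
):
    """Merge network nodes by cluster label into a simplified network.

    One node per cluster; an edge between cluster nodes iff any member edge
    crossed them (self-loops dropped); edge enzyme annotations are the union
    of member-edge labels.
    """
    import networkx as nx

    label_of = dict(zip(clusters.items, clusters.labels))
    g = nx.DiGraph()
    for lab in set(clusters.labels):
        members = [k for k in clusters.items if label_of[k] == lab]
        g.add_node(lab, members=members, size=len(members))
    for u, v, d in network.graph.edges(data=True):
        if u not in label_of or v not in label_of:
            continue
        lu, lv = label_of[u], label_of[v]
        if lu == lv:
            continue
        enzyme = d.get("enzyme", UNANNOTATED)
        if g.has_edge(lu, lv):
            g.edges[lu, lv]["enzymes"].add(enzyme)
        else:
            g.add_edge(lu, lv, enzymes={enzyme})
    return g
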