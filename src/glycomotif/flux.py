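"""Product-substrate abundance ratios along network edges as flux proxies.

Substructure abundance measures the total amount of a structure ever
synthesized (secreted as-is or extended further), so the ratio of a child
substructure's abundance to its parent's estimates the fraction of the
substrate pool converted by that biosynthetic step.  Ratios grouped by the
annotating enzyme give per-sample ratio distributions that can be compared
across conditions (e.g. knockout vs wild type) with a rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import scipy.stats

from .network import SubstructureNetwork, UNANNOTATED
from .substructure import SubstructureProfile

__all__ = [
    "EdgeRatio",
    "edge_ratios",
    "ratios_frame",
    "enzyme_ratio_distribution",
    "compare_ratio_distributions",
]


@dataclass(frozen=True)
class EdgeRatio:
    parent: str
    child: str
    sample_id: str
    enzyme: str
    ratio: float
    defined: bool


def edge_ratios(
    network: SubstructureNetwork,
    profile: SubstructureProfile,
    floor: float = 1e-12,
) -> list[EdgeRatio]:
    """Child/parent abundance ratio for every network edge in one sample.

    Ratios are undefined (``defined=False``) when the parent abundance falls
    below ``floor``; defined ratios lie in [0, 1] by containment
    monotonicity.  Multi-parent children yield one ratio per incoming edge.
    """
    out = []
    for u, v, d in network.graph.edges(data=True):
        pv = profile.values[u]
        cv = profile.values[v]
        if pv < 0 or cv < 0:
            raise ValueError("negative substructure abundance")
        enzyme = d.get("enzyme", UNANNOTATED)
        if pv < floor:
            out.append(EdgeRatio(u, v, profile.sample_id, enzyme, float("nan"), False))
            continue
        ratio = cv / pv
        if ratio > 1 + 1e-9:
            raise ValueError(
                f"ratio {ratio} exceeds 1: containment monotonicity violated "
                f"for edge {u!r} -> {v!r}"
            )
        out.append(EdgeRatio(u, v, profile.sample_id, enzyme, min(ratio, 1.0), True))
    return out


def ratios_frame(ratios: list[EdgeRatio]) -> pd.DataFrame:
    """Long-format table: parent, child, enzyme, sample, ratio, defined."""
    return pd.DataFrame(
        [
            {
                "parent": r.parent,
                "child": r.child,
                "enzyme": r.enzyme,
                "sample": r.sample_id,
                "ratio": r.ratio,
                "defined": r.defined,
            }
            for r in ratios
        ]
    )


def enzyme_ratio_distribution(
    ratios: list[EdgeRatio],
    enzyme: str,
    shared_edges_only: bool = False,
) -> dict[str, list[float]]:
    """Per-sample collections of defined ratios for one enzyme.

    With ``shared_edges_only``, only edges whose ratio is defined in every
    sample are kept, so group sizes are equal across samples.
    """
    known = {r.enzyme for r in ratios}
    if enzyme not in known:
        raise KeyError(f"unknown enzyme label {enzyme!r}; have {sorted(known)}")
    mine = [r for r in ratios if r.enzyme == enzyme]
    samples = sorted({r.sample_id for r in mine})
    if shared_edges_only:
        by_edge: dict[tuple[str, str], set[str]] = {}
        for r in mine:
            if r.defined:
                by_edge.setdefault((r.parent, r.child), set()).add(r.sample_id)
        shared = {e for e, s in by_edge.items() if s == set(samples)}
        mine = [r for r in mine if (r.parent, r.child) in shared]
    out: dict[str, list[float]] = {s: [] for s in samples}
    for r in mine:
        if r.defined:
            out[r.sample_id].append(r.ratio)
    return out


def compare_ratio_distributions(
    group_a: list[float],
    group_b: list[float],
    alternative: str = "less",
) -> float:
    """One-sided two-sample Wilcoxon rank-sum p-value comparing an enzyme's
    ratio distributions in two samples."""
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    pooled = list(group_a) + list(group_b)
    no_ties = len(set(pooled)) == len(pooled)
    method = "exact" if (no_ties and len(pooled) <= 30) else "asymptotic"
    res = scipy.stats.mannwhitneyu(
        group_a, group_b, alternative=alternative, method=method
    )
    return float(res.pvalue)
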