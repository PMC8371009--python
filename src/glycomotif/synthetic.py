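"""Synthetic biosynthetic networks, glycan sets and glycoprofiles with
known ground truth.

The generator emulates the structure of real glycoprofiling studies:

* a biosynthetic universe grown from a core by enzyme rules (each enzyme
  adds one monosaccharide via a fixed linkage onto a matching acceptor);
* steady-state pool propagation — each enzyme converts a fraction ``f`` of
  its substrate pool to the product, the remainder is secreted — which is
  exactly the semantics under which the child/parent substructure abundance
  ratio recovers ``f``;
* enzyme knockouts (``f = 0``) that zero whole network branches, as in
  glycoengineering panels;
* multiplicative log-normal measurement noise before renormalization to
  relative abundance, the standard error model for MS/HPLC relative
  quantitation.

The default universe is a milk-oligosaccharide-like pathway on a lactose
core (the reducing-end glucose occurs nowhere else, so every core-anchored
substructure embeds uniquely and pool abundances are identifiable).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .glycan_io import (
    GlycanIOError,
    GlycanTree,
    Glycoprofile,
    Linkage,
    Monosaccharide,
    serialize_glycoct,
)

__all__ = [
    "SimEnzyme",
    "SimulationConfig",
    "SimulationResult",
    "lactose_core",
    "default_enzymes",
    "linear_chain_enzymes",
    "build_universe",
    "simulate",
    "knockout_panel",
    "dilution_series",
    "null_matrix",
    "make_fixture_suite",
]


@dataclass(frozen=True)
class SimEnzyme:
    """One simulated glycosyltransferase: adds ``residue`` via ``linkage``
    onto any acceptor node with symbol ``acceptor`` lacking a child at that
    position, converting fraction ``f`` of the substrate pool."""

    name: str
    residue: str
    anomer: str
    parent_pos: int
    acceptor: str
    f: float
    child_pos: int = 1

    def linkage(self) -> Linkage:
        return Linkage(self.parent_pos, self.child_pos)


def lactose_core() -> GlycanTree:
    """Gal b1-4 Glc: the reducing-end core of milk oligosaccharides."""
    return GlycanTree(
        {1: Monosaccharide("Glc", "b"), 2: Monosaccharide("Gal", "b")},
        [(1, 2, Linkage(4, 1))],
    )


def default_enzymes() -> list[SimEnzyme]:
    """HMO-like enzyme set with realistic conversion fractions."""
    return [
        SimEnzyme("b3GnT", "GlcNAc", "b", 3, "Gal", 0.70),
        SimEnzyme("b3GalT", "Gal", "b", 3, "GlcNAc", 0.80),
        SimEnzyme("ST6GnT", "Neu5Ac", "a", 6, "GlcNAc", 0.50, child_pos=2),
        SimEnzyme("ST3GalT", "Neu5Ac", "a", 3, "Gal", 0.45, child_pos=2),
        SimEnzyme("FUT2", "Fuc", "a", 2, "Gal", 0.40),
    ]


def linear_chain_enzymes(fs: list[float]) -> tuple[GlycanTree, list[SimEnzyme]]:
    """A strictly linear cascade A -> A-B -> A-B-C ... with given fractions.

    Useful for closed-form checks: with conversion fraction f at every step
    the secreted abundances follow the geometric pattern (1-f), f(1-f), ...
    and every edge ratio equals f.
    """
    symbols = ["A", "B", "C", "D", "E", "F", "G", "H"]
    if len(fs) > len(symbols) - 1:
        raise ValueError("cascade too long")
    core = GlycanTree({1: Monosaccharide("A", "b")}, [])
    enzymes = [
        SimEnzyme(f"E{i+1}", symbols[i + 1], "b", 3, symbols[i], f)
        for i, f in enumerate(fs)
    ]
    return core, enzymes


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    core: GlycanTree = field(default_factory=lactose_core)
    enzymes: tuple[SimEnzyme, ...] = None  # type: ignore[assignment]
    max_size: int = 8
    max_structures: int = 400
    knockouts: frozenset[str] = frozenset()
    noise_sd: float = 0.1
    n_samples: int = 8
    #: relative-abundance quantitation floor: secreted species below this
    #: share of total secreted mass go unobserved, giving profiles the
    #: sparsity of real MS/HPLC glycoprofiles (1% is the usual reporting
    #: threshold for HPLC peak quantitation)
    detection_limit: float = 0.01

    def __post_init__(self) -> None:
        if self.enzymes is None:
            object.__setattr__(self, "enzymes", tuple(default_enzymes()))
        names = {e.name for e in self.enzymes}
        unknown = self.knockouts - names
        if unknown:
            raise ValueError(f"knockouts reference unknown enzymes: {sorted(unknown)}")


def _attach(tree: GlycanTree, node: int, enz: SimEnzyme) -> GlycanTree:
    new_id = max(tree.nodes) + 1
    nodes = dict(tree.nodes)
    nodes[new_id] = Monosaccharide(enz.residue, enz.anomer)
    edges = list(tree.edges) + [(node, new_id, enz.linkage())]
    return GlycanTree(nodes, edges)


def build_universe(
    core: GlycanTree,
    enzymes,
    max_size: int,
    max_structures: int = 400,
):
    """Enzyme closure of the core: all reachable structures and reactions.

    Returns ``(structures, edges)`` where ``structures`` maps canonical key
    to tree and ``edges`` maps ``(parent_key, child_key)`` to the enzyme
    name (first applicable in name order on ties).
    """
    structures: dict[str, GlycanTree] = {core.key: core}
    edges: dict[tuple[str, str], str] = {}
    frontier = [core]
    while frontier:
        tree = frontier.pop(0)
        if len(tree) >= max_size:
            continue
        for enz in sorted(enzymes, key=lambda e: e.name):
            for node in sorted(tree.nodes):
                if tree.nodes[node].symbol != enz.acceptor:
                    continue
                if any(
                    lk.parent_pos == enz.parent_pos for _, lk in tree.children(node)
                ):
                    continue
                child = _attach(tree, node, enz)
                ckey = child.key
                if ckey not in structures:
                    if len(structures) >= max_structures:
                        continue
                    structures[ckey] = child
                    frontier.append(child)
                edges.setdefault((tree.key, ckey), enz.name)
    return structures, edges


def _steady_state(structures, edges, enzymes, knockouts):
    """Propagate unit input through the DAG; returns (pools, secreted,
    effective per-edge conversion fractions)."""
    f_of = {e.name: (0.0 if e.name in knockouts else e.f) for e in enzymes}
    order = sorted(structures, key=lambda k: (len(structures[k]), k))
    out_edges: dict[str, list[tuple[str, str]]] = {k: [] for k in structures}
    for (p, c), enz in edges.items():
        out_edges[p].append((c, enz))
    pools = {k: 0.0 for k in structures}
    pools[order[0]] = 1.0
    secreted = {}
    eff_f: dict[tuple[str, str], float] = {}
    for key in order:
        pool = pools[key]
        outs = sorted(out_edges[key])
        total_f = sum(f_of[enz] for _, enz in outs)
        scale = 1.0 / total_f if total_f > 1 else 1.0
        for child, enz in outs:
            fe = f_of[enz] * scale
            eff_f[(key, child)] = fe
            pools[child] += pool * fe
        secreted[key] = pool * max(0.0, 1.0 - min(total_f, 1.0))
    return pools, secreted, eff_f


@dataclass
class SimulationResult:
    config: SimulationConfig
    structures: dict[str, GlycanTree]
    edges: dict[tuple[str, str], str]  # (parent, child) -> enzyme
    pools: dict[str, float]
    secreted: dict[str, float]
    true_edge_f: dict[tuple[str, str], float]
    true_edge_ratio: dict[tuple[str, str], float]
    profiles: list[Glycoprofile]

    def secreted_glycans(self) -> dict[str, GlycanTree]:
        return {k: self.structures[k] for k, v in self.secreted.items() if v > 0}


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run one condition: build the universe, propagate pools, observe
    ``n_samples`` noisy normalized glycoprofiles."""
    rng = np.random.default_rng(config.seed)
    structures, edges = build_universe(
        config.core, config.enzymes, config.max_size, config.max_structures
    )
    pools, secreted, eff_f = _steady_state(
        structures, edges, config.enzymes, config.knockouts
    )
    total_secreted = sum(secreted.values())
    if total_secreted <= 0:
        raise GlycanIOError("zero secreted mass: every branch fully converted")
    ratio = {
        (p, c): (pools[c] / pools[p] if pools[p] > 0 else float("nan"))
        for (p, c) in edges
    }
    keys = [
        k for k, v in secreted.items()
        if v / total_secreted > config.detection_limit
    ]
    if not keys:
        raise GlycanIOError("no secreted species above the detection limit")
    base = np.array([secreted[k] for k in keys], dtype=float)
    profiles = []
    for i in range(config.n_samples):
        noise = rng.lognormal(mean=0.0, sigma=config.noise_sd, size=len(base))
        obs = base * noise
        obs = obs / obs.sum()
        profiles.append(
            Glycoprofile(
                sample_id=f"S{i+1}",
                abundances={k: float(v) for k, v in zip(keys, obs)},
                structures={k: structures[k] for k in keys},
                metadata={"knockouts": sorted(config.knockouts)},
            )
        )
    return SimulationResult(
        config, structures, edges, pools, secreted, eff_f, ratio, profiles
    )


def knockout_panel(
    seed: int = 0,
    conditions: list[frozenset[str]] | None = None,
    samples_per_condition: int = 1,
    noise_sd: float = 0.1,
    max_size: int = 8,
) -> dict[str, SimulationResult]:
    """A WT + knockout panel over the default universe.

    Sample ids are prefixed by the condition name (``WT`` or ``KO.<enzyme>``);
    all conditions share one structural universe.
    """
    if conditions is None:
        conditions = [
            frozenset(),
            frozenset({"FUT2"}),
            frozenset({"ST3GalT"}),
            frozenset({"ST6GnT"}),
            frozenset({"b3GalT"}),
        ]
    out = {}
    for i, ko in enumerate(conditions):
        name = "WT" if not ko else "KO." + "/".join(sorted(ko))
        cfg = SimulationConfig(
            seed=seed + 1000 * i,
            knockouts=ko,
            noise_sd=noise_sd,
            n_samples=samples_per_condition,
            max_size=max_size,
        )
        res = simulate(cfg)
        for j, p in enumerate(res.profiles):
            p.sample_id = f"{name}.{j+1}" if samples_per_condition > 1 else name
        out[name] = res
    return out


def dilution_series(
    seed: int = 0,
    factors: tuple[float, ...] = (1.0, 2.0, 0.5),
    n_features: int = 40,
    noise_sd: float = 0.05,
) -> tuple[pd.DataFrame, tuple[float, ...]]:
    """Features x samples matrix where each sample is a known dilution of a
    common profile plus multiplicative noise; ground truth = the factors."""
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_features)
    cols = {}
    for i, f in enumerate(factors):
        noise = rng.lognormal(mean=0.0, sigma=noise_sd, size=n_features)
        cols[f"D{i+1}"] = base * f * noise
    return pd.DataFrame(cols, index=[f"feat{i}" for i in range(n_features)]), factors


def null_matrix(
    seed: int = 0, n_structures: int = 20, n_per_group: int = 10
) -> tuple[pd.DataFrame, pd.Series]:
    """Structures x samples matrix with no group effect (null panel for
    FDR / type-I-error checks)."""
    rng = np.random.default_rng(seed)
    cols = [f"a{i}" for i in range(n_per_group)] + [f"b{i}" for i in range(n_per_group)]
    mat = pd.DataFrame(
        rng.normal(size=(n_structures, 2 * n_per_group)),
        index=[f"s{i}" for i in range(n_structures)],
        columns=cols,
    )
    groups = pd.Series(
        ["A"] * n_per_group + ["B"] * n_per_group, index=cols
    )
    return mat, groups


def epo_scale_panel(seed: int = 0, n_samples: int = 16, max_size: int = 10):
    """A 16-condition panel at the scale of a glycoengineering study:
    one sample per condition, conditions ranging from WT-like to severe
    multi-enzyme knockouts."""
    enzymes = [e.name for e in default_enzymes()]
    conditions: list[frozenset[str]] = [frozenset()]
    singles = [frozenset({e}) for e in enzymes]
    pairs = [
        frozenset({a, b})
        for i, a in enumerate(enzymes)
        for b in enzymes[i + 1:]
    ]
    for ko in singles + pairs:
        if len(conditions) >= n_samples:
            break
        conditions.append(ko)
    return knockout_panel(
        seed=seed, conditions=conditions, samples_per_condition=1,
        max_size=max_size,
    )


def make_fixture_suite(out_dir, seed: int = 0) -> dict[str, Path]:
    """Write the standard test scenarios to disk (GlycoCT structures,
    abundance tables, enzyme rules, ground-truth JSON).  Deterministic given
    the seed; all files parse back through glycan_io."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _write(name: str, text: str) -> None:
        p = out / name
        p.write_text(text)
        written[name] = p

    # knockout panel
    panel = knockout_panel(seed=seed, samples_per_condition=3)
    all_structures: dict[str, GlycanTree] = {}
    table: dict[str, dict[str, float]] = {}
    for res in panel.values():
        all_structures.update(res.structures)
        for p in res.profiles:
            table[p.sample_id] = dict(p.abundances)
    id_of = {k: f"X{i+1}" for i, k in enumerate(sorted(all_structures,
             key=lambda k: (len(all_structures[k]), k)))}
    _write(
        "panel_structures.glycoct",
        "\n".join(
            serialize_glycoct(all_structures[k], name=id_of[k])
            for k in id_of
        ),
    )
    df = pd.DataFrame(
        {
            s: {id_of[k]: v for k, v in ab.items()}
            for s, ab in table.items()
        }
    ).fillna(0.0)
    _write("panel_abundance.csv", df.to_csv())
    truth = {
        name: {
            "knockouts": sorted(res.config.knockouts),
            "pools": res.pools,
            "secreted": res.secreted,
            "edges": [
                {"parent": p, "child": c, "enzyme": e,
                 "true_ratio": res.true_edge_ratio[(p, c)]}
                for (p, c), e in sorted(res.edges.items())
            ],
        }
        for name, res in panel.items()
    }
    _write("panel_truth.json", json.dumps(truth, indent=1, sort_keys=True))
    rules = [
        {
            "enzyme": e.name,
            "residue": e.residue,
            "anomer": e.anomer,
            "parent_pos": e.parent_pos,
            "child_pos": e.child_pos,
            "context": e.acceptor,
        }
        for e in default_enzymes()
    ]
    _write("panel_rules.yaml", yaml.safe_dump(rules, sort_keys=True))

    # dilution series for PQN
    dil, factors = dilution_series(seed=seed)
    _write("dilution.csv", dil.to_csv())
    _write("dilution_truth.json", json.dumps({"factors": list(factors)}))

    # null panel for FDR / type-I error
    nm, groups = null_matrix(seed=seed)
    _write("null_matrix.csv", nm.to_csv())
    _write("null_groups.csv", groups.rename("group").to_csv())

    # linear cascade with closed-form ground truth
    core, enzymes = linear_chain_enzymes([0.5, 0.5, 0.5, 0.5])
    cascade = simulate(
        SimulationConfig(seed=seed, core=core, enzymes=tuple(enzymes),
                         max_size=5, noise_sd=0.0, n_samples=1)
    )
    _write(
        "cascade_truth.json",
        json.dumps(
            {
                "secreted": cascade.secreted,
                "edge_f": {f"{p}->{c}": v
                           for (p, c), v in cascade.true_edge_f.items()},
            },
            indent=1, sort_keys=True,
        ),
    )
    return written
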