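"""Glycan structures, canonical forms and profile I/O.

Glycans are rooted labeled trees: nodes are monosaccharides (symbol +
anomeric state), edges carry glycosidic linkage positions, and the root is
the reducing-end residue.  Structures are read and written in a condensed
GlycoCT dialect restricted to RES/LIN topology sections, e.g.::

    RES
    1b:b-GlcNAc
    2b:b-Gal
    LIN
    1:1(4+1)2

Residue lines are ``<id>b:<anomer>-<symbol>`` with anomer ``a``/``b``/``x``
(x = unknown); linkage lines are ``<n>:<parent>(<parentpos>+<childpos>)<child>``
with ``-1`` for an unknown position.  Canonical keys make structural identity
decidable: two trees receive equal keys iff they are isomorphic as rooted
trees respecting symbols, anomeric states and linkage positions.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "Monosaccharide",
    "Linkage",
    "GlycanTree",
    "Glycoprofile",
    "GlycanIOError",
    "DEFAULT_SYMBOLS",
    "parse_glycoct",
    "parse_glycoct_records",
    "serialize_glycoct",
    "canonical_key",
    "expand_ambiguous",
    "read_profile_table",
]


class GlycanIOError(ValueError):
    """Malformed structure document or profile table."""


#: Controlled vocabulary of monosaccharide symbols accepted by default.
#: Generic classes (Hex, HexNAc, dHex) are included for composition-style
#: data; the registry is extensible via ``register_symbol``.
DEFAULT_SYMBOLS = {
    "Glc", "Gal", "Man", "GlcNAc", "GalNAc", "Fuc", "Xyl",
    "Neu5Ac", "Neu5Gc", "NeuAc", "NeuGc", "Kdn",
    "Hex", "HexNAc", "dHex", "Pent",
    # single-letter symbols used by synthetic fixtures and tests
    "A", "B", "C", "D", "E", "F", "G", "H",
}

_ANOMERS = ("a", "b", "x")


def register_symbol(symbol: str) -> None:
    """Add a monosaccharide token to the accepted registry."""
    DEFAULT_SYMBOLS.add(symbol)


@dataclass(frozen=True)
class Monosaccharide:
    symbol: str
    anomer: str = "x"  # 'a' alpha, 'b' beta, 'x' unknown

    def __post_init__(self) -> None:
        if self.anomer not in _ANOMERS:
            raise GlycanIOError(f"invalid anomeric state {self.anomer!r}")


@dataclass(frozen=True)
class Linkage:
    """Glycosidic linkage; ``None`` encodes an unknown position.

    Unknown compares equal only to itself for identity purposes (canonical
    keys); pattern matching treats pattern-side unknowns as wildcards (see
    :mod:`glycomotif.substructure`).
    """

    parent_pos: int | None = None
    child_pos: int | None = 1

    def __post_init__(self) -> None:
        for pos in (self.parent_pos, self.child_pos):
            if pos is not None and not (1 <= pos <= 9):
                raise GlycanIOError(f"linkage position {pos} outside 1-9")

    def token(self) -> str:
        pp = "-1" if self.parent_pos is None else str(self.parent_pos)
        cp = "-1" if self.child_pos is None else str(self.child_pos)
        return f"{pp}+{cp}"


class GlycanTree:
    """Rooted labeled tree of monosaccharides.

    ``nodes`` maps integer node ids to :class:`Monosaccharide`; ``edges`` is a
    list of ``(parent_id, child_id, Linkage)``.  The constructor validates
    connectivity, acyclicity and the single-parent property.
    """

    __slots__ = ("nodes", "edges", "root", "_children", "_key")

    def __init__(
        self,
        nodes: dict[int, Monosaccharide],
        edges: list[tuple[int, int, Linkage]],
        root: int | None = None,
    ) -> None:
        if not nodes:
            raise GlycanIOError("empty glycan")
        self.nodes = dict(nodes)
        self.edges = list(edges)
        parents: dict[int, int] = {}
        children: dict[int, list[tuple[int, Linkage]]] = {i: [] for i in self.nodes}
        for p, c, lk in self.edges:
            if p not in self.nodes or c not in self.nodes:
                raise GlycanIOError(f"edge ({p},{c}) references unknown node")
            if c in parents:
                raise GlycanIOError(f"node {c} has multiple parents")
            parents[c] = p
            children[p].append((c, lk))
        roots = [i for i in self.nodes if i not in parents]
        if len(roots) != 1:
            if not roots:
                raise GlycanIOError(
                    "cyclic structure rejected: every residue has a parent, "
                    "so the linkages form a cycle"
                )
            raise GlycanIOError(
                f"structure must have exactly one reducing end, found {len(roots)}"
            )
        self.root = roots[0] if root is None else root
        if root is not None and root != roots[0]:
            raise GlycanIOError("declared root is not the parentless node")
        # cycle/connectivity check: iterative DFS from root
        seen: set[int] = set()
        stack = [self.root]
        while stack:
            v = stack.pop()
            if v in seen:
                raise GlycanIOError("cyclic structure rejected: cycle reached "
                                    f"node {v}")
            seen.add(v)
            stack.extend(c for c, _ in children[v])
        if seen != set(self.nodes):
            missing = sorted(set(self.nodes) - seen)
            # unreachable residues that all have parents form a detached cycle
            if all(m in parents for m in missing):
                raise GlycanIOError(
                    f"cyclic structure rejected: cycle among residues {missing}"
                )
            raise GlycanIOError(f"structure not connected; unreachable nodes {missing}")
        self._children = children
        self._key: str | None = None

    def __len__(self) -> int:
        return len(self.nodes)

    def children(self, node: int) -> list[tuple[int, Linkage]]:
        return self._children[node]

    def subtree_size(self, node: int) -> int:
        return 1 + sum(self.subtree_size(c) for c, _ in self._children[node])

    @property
    def key(self) -> str:
        if self._key is None:
            self._key = canonical_key(self)
        return self._key

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GlycanTree) and self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GlycanTree({len(self)} residues, key={self.key!r})"


# ---------------------------------------------------------------------------
# canonical form


def _canonical_subkey(tree: GlycanTree, node: int) -> str:
    mono = tree.nodes[node]
    kids = []
    for child, lk in tree.children(node):
        ck = _canonical_subkey(tree, child)
        cm = tree.nodes[child]
        # sort children by (symbol, anomer, parent-position, recursive key)
        sort_pos = -1 if lk.parent_pos is None else lk.parent_pos
        kids.append(((cm.symbol, cm.anomer, sort_pos, ck), f"{lk.token()}:{ck}"))
    kids.sort(key=lambda t: t[0])
    head = f"{mono.symbol}|{mono.anomer}"
    if not kids:
        return head
    return head + "(" + ",".join(s for _, s in kids) + ")"


def canonical_key(tree: GlycanTree) -> str:
    """Text key invariant under child reordering, distinguishing everything else."""
    return _canonical_subkey(tree, tree.root)


# ---------------------------------------------------------------------------
# GlycoCT dialect

_RES_RE = re.compile(r"^(\d+)b:([abxo])-([A-Za-z][A-Za-z0-9]*)$")
_LIN_RE = re.compile(r"^(\d+):(\d+)[od]?\((-?\d+)\+(-?\d+)\)(\d+)[nd]?$")


def parse_glycoct(text: str, symbols: set[str] | None = None) -> GlycanTree:
    """Parse one GlycoCT RES/LIN document into a :class:`GlycanTree`.

    Raises :class:`GlycanIOError` for cycles, unknown residue tokens, or
    malformed lines.
    """
    registry = DEFAULT_SYMBOLS if symbols is None else symbols
    section = None
    nodes: dict[int, Monosaccharide] = {}
    edges: list[tuple[int, int, Linkage]] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line in ("RES", "LIN"):
            section = line
            continue
        if line == "UND":
            raise GlycanIOError(
                "UND sections are not supported; pre-expand underdetermined "
                "structures into explicit candidates"
            )
        if section == "RES":
            m = _RES_RE.match(line)
            if not m:
                raise GlycanIOError(f"malformed RES line: {line!r}")
            idx, anomer, symbol = int(m.group(1)), m.group(2), m.group(3)
            if symbol not in registry:
                raise GlycanIOError(f"unknown residue token {symbol!r}")
            if anomer == "o":  # open-chain treated as unknown
                anomer = "x"
            nodes[idx] = Monosaccharide(symbol, anomer)
        elif section == "LIN":
            m = _LIN_RE.match(line)
            if not m:
                raise GlycanIOError(f"malformed LIN line: {line!r}")
            _, parent, pp, cp, child = (int(g) for g in m.groups())
            lk = Linkage(None if pp < 0 else pp, None if cp < 0 else cp)
            edges.append((parent, child, lk))
        else:
            raise GlycanIOError(f"content outside RES/LIN sections: {line!r}")
    if not nodes:
        raise GlycanIOError("document contains no RES entries")
    return GlycanTree(nodes, edges)


def parse_glycoct_records(text: str) -> dict[str, GlycanTree]:
    """Parse a multi-record document (records separated by blank lines).

    A record may begin with ``ID <name>``; unnamed records are numbered
    ``G1, G2, ...`` in order of appearance.
    """
    records: dict[str, GlycanTree] = {}
    chunks = re.split(r"\n\s*\n", text.strip())
    for i, chunk in enumerate(chunks, start=1):
        if not chunk.strip():
            continue
        lines = chunk.strip().splitlines()
        name = f"G{i}"
        if lines[0].startswith("ID "):
            name = lines[0][3:].strip()
            lines = lines[1:]
        records[name] = parse_glycoct("\n".join(lines))
    return records


def serialize_glycoct(tree: GlycanTree, name: str | None = None) -> str:
    """Serialize deterministically: children emitted in canonical order.

    Two isomorphic trees therefore produce byte-identical text.
    """
    order: list[int] = []

    def visit(node: int) -> None:
        order.append(node)
        kids = []
        for child, lk in tree.children(node):
            cm = tree.nodes[child]
            sort_pos = -1 if lk.parent_pos is None else lk.parent_pos
            kids.append(((cm.symbol, cm.anomer, sort_pos,
                          _canonical_subkey(tree, child)), child))
        kids.sort(key=lambda t: t[0])
        for _, child in kids:
            visit(child)

    visit(tree.root)
    renum = {node: i + 1 for i, node in enumerate(order)}
    link_of = {c: (p, lk) for p, c, lk in tree.edges}
    out = []
    if name is not None:
        out.append(f"ID {name}")
    out.append("RES")
    for node in order:
        m = tree.nodes[node]
        out.append(f"{renum[node]}b:{m.anomer}-{m.symbol}")
    out.append("LIN")
    n = 0
    for node in order:
        if node in link_of:
            p, lk = link_of[node]
            n += 1
            out.append(f"{n}:{renum[p]}({lk.token().replace('+', '+')}){renum[node]}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# profiles


@dataclass
class Glycoprofile:
    """One sample's relative glycan abundances g_ij / sum_j g_ij.

    ``abundances`` maps canonical keys to relative abundance; ``structures``
    resolves each key to its tree.
    """

    sample_id: str
    abundances: dict[str, float]
    structures: dict[str, GlycanTree]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.abundances.items():
            if v < 0:
                raise GlycanIOError(f"negative abundance for {k!r}")
            if k not in self.structures:
                raise GlycanIOError(f"abundance key {k!r} has no structure")

    @property
    def total(self) -> float:
        return sum(self.abundances.values())

    def glycans(self) -> list[GlycanTree]:
        return [self.structures[k] for k in self.abundances]


def expand_ambiguous(
    candidates: list[GlycanTree], abundance: float
) -> list[tuple[GlycanTree, float]]:
    """Split an ambiguous topology's abundance equally over its n candidates.

    Each candidate receives ``abundance / n``; total abundance is conserved.
    """
    if not candidates:
        raise GlycanIOError("ambiguous glycan with no candidate structures")
    if abundance < 0:
        raise GlycanIOError("negative abundance")
    share = abundance / len(candidates)
    return [(t, share) for t in candidates]


def read_profile_table(
    table,
    structures: dict[str, GlycanTree],
    *,
    sep: str | None = None,
    tol: float = 1e-9,
) -> list[Glycoprofile]:
    """Read a glycans x samples abundance table into normalized profiles.

    ``table`` is a path or file-like; the first column holds glycan ids that
    must resolve in ``structures``; remaining columns are samples.  Missing
    cells count as 0; each sample is normalized to relative abundance.
    """
    if isinstance(table, (str, bytes)) and "\n" in str(table):
        table = io.StringIO(str(table))
    df = pd.read_csv(table, sep=sep, engine="python", index_col=0)
    df = df.fillna(0.0).astype(float)
    missing = [str(g) for g in df.index if str(g) not in structures]
    if missing:
        raise GlycanIOError(f"glycan ids without structures: {missing}")
    if (df.values < 0).any():
        raise GlycanIOError("negative raw abundances")
    profiles = []
    for sample in df.columns:
        col = df[sample]
        total = float(col.sum())
        if total <= 0:
            raise GlycanIOError(f"sample {sample!r} has zero total abundance")
        abund: dict[str, float] = {}
        strmap: dict[str, GlycanTree] = {}
        for gid, raw in col.items():
            if raw == 0:
                continue
            tree = structures[str(gid)]
            key = tree.key
            abund[key] = abund.get(key, 0.0) + float(raw) / total
            strmap[key] = tree
        prof = Glycoprofile(str(sample), abund, strmap)
        assert abs(prof.total - 1.0) <= tol * max(1.0, prof.total)
        profiles.append(prof)
    return profiles
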