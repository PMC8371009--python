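"""Substructure-style aggregation for composition-only glycan data.

Site-specific glycoproteomics often reports only monosaccharide-class
counts, e.g. HexNAc2Hex5Fuc1, without linkage or topology.  The
substructure idea carries over on the count lattice: the aggregated
abundance of a query composition (p, q, r, ...) is the summed abundance of
every measured composition componentwise >= the query — every structure
that must have passed through an intermediate with at least those counts.
Probabilistic quotient normalization (PQN) is provided for the preceding
normalization step.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Composition",
    "DEFAULT_CLASSES",
    "parse_composition",
    "compositional_substructure",
    "pqn_normalize",
]

DEFAULT_CLASSES = ("HexNAc", "Hex", "Fuc", "NeuAc", "NeuGc")

_COMP_RE = re.compile(r"([A-Za-z]+?)(\d+)")


@dataclass(frozen=True)
class Composition:
    """Monosaccharide-class count vector, e.g. HexNAc2Hex5Fuc1."""

    counts: tuple[tuple[str, int], ...] = field(default_factory=tuple)

    @classmethod
    def from_dict(cls, d: dict[str, int], classes=DEFAULT_CLASSES) -> "Composition":
        for k, v in d.items():
            if k not in classes:
                raise KeyError(f"unknown monosaccharide class {k!r}")
            if v < 0:
                raise ValueError("negative count")
        return cls(tuple((c, int(d.get(c, 0))) for c in classes))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def vector(self, classes=DEFAULT_CLASSES) -> np.ndarray:
        d = self.as_dict()
        return np.array([d.get(c, 0) for c in classes], dtype=int)

    def __str__(self) -> str:
        return "".join(f"{c}{n}" for c, n in self.counts if n > 0) or "Empty"


def parse_composition(text: str, classes=DEFAULT_CLASSES) -> Composition:
    """Parse 'HexNAc2Hex5Fuc1'-style tokens."""
    found: dict[str, int] = {}
    pos = 0
    for m in _COMP_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed composition {text!r}")
        pos = m.end()
        cls_, n = m.group(1), int(m.group(2))
        if cls_ not in classes:
            raise KeyError(f"unknown monosaccharide class {cls_!r}")
        found[cls_] = found.get(cls_, 0) + n
    if pos != len(text):
        raise ValueError(f"malformed composition {text!r}")
    return Composition.from_dict(found, classes)


def compositional_substructure(
    table: dict[Composition, float] | pd.Series,
    query: Composition,
) -> float:
    """Aggregated abundance of all compositions componentwise >= query."""
    if isinstance(table, pd.Series):
        items = [(parse_composition(str(k)) if not isinstance(k, Composition) else k, v)
                 for k, v in table.items()]
    else:
        items = list(table.items())
    qv = query.vector()
    total = 0.0
    for comp, abundance in items:
        if abundance < 0:
            raise ValueError("negative abundance")
        if np.all(comp.vector() >= qv):
            total += float(abundance)
    return total


def pqn_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Probabilistic quotient normalization of a features x samples matrix.

    The reference is the feature-wise median sample; each sample is divided
    by the median of its feature-wise quotients against the reference
    (zero features excluded).  Idempotent and invariant to per-sample
    scaling.
    """
    if matrix.shape[1] < 2:
        raise ValueError("PQN needs at least two samples")
    vals = matrix.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative abundances")
    if (vals.sum(axis=0) == 0).any():
        zero = [str(c) for c, s in zip(matrix.columns, vals.sum(axis=0)) if s == 0]
        raise ValueError(f"all-zero samples: {zero}")
    reference = np.median(vals, axis=1)
    out = vals.copy()
    for j in range(vals.shape[1]):
        mask = (reference > 0) & (vals[:, j] > 0)
        if not mask.any():
            raise ValueError(
                f"sample {matrix.columns[j]!r} shares no nonzero features "
                "with the reference"
            )
        quotients = vals[mask, j] / reference[mask]
        out[:, j] = vals[:, j] / np.median(quotients)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
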