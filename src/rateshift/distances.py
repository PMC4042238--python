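"""Pairwise genetic distances and neighbor-joining trees.

Distances are estimated per species pair with pairwise deletion: a site
is usable for a pair only if both sequences carry an unambiguous base
there.  Closed-form correction under JC69 (equal rates and frequencies)
or K80 (transition/transversion distinction) is applied on top of the
observed proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

BASES = frozenset("ACGT")
PURINES = frozenset("AG")

MODELS = ("p", "jc69", "k80")


class SaturationError(ValueError):
    """Observed divergence outside the domain of the distance formula."""


@dataclass(frozen=True)
class DistanceEstimate:
    value: float
    model: str
    sites_used: int

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("distance must be >= 0")
        if self.sites_used < 1:
            raise ValueError("sites_used must be >= 1")


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
            raise ValueError("matrix must be symmetric with zero diagonal")
        if not np.isfinite(v).all() or (v < 0).any():
            raise ValueError("matrix entries must be finite and nonnegative")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def _usable_counts(a: str, b: str) -> tuple[int, int, int]:
    """(usable sites, transitions, transversions) under pairwise deletion."""
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        raise ValueError("sequences must have equal aligned length")
    usable = ts = tv = 0
    for x, y in zip(a, b):
        if x not in BASES or y not in BASES:
            continue
        usable += 1
        if x != y:
            if (x in PURINES) == (y in PURINES):
                ts += 1
            else:
                tv += 1
    return usable, ts, tv


def p_distance(a: str, b: str) -> DistanceEstimate:
    """Observed proportion of differing sites (mismatches / usable sites)."""
    usable, ts, tv = _usable_counts(a, b)
    if usable == 0:
        raise ValueError("no usable sites (all gapped or ambiguous)")
    return DistanceEstimate((ts + tv) / usable, "p", usable)


def jc69_from_p(p: float) -> float:
    """JC69 correction d = -(3/4) ln(1 - 4p/3); undefined for p >= 3/4."""
    if p >= 0.75:
        raise SaturationError(f"p = {p:.4f} >= 3/4: JC69 distance undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc69_distance(a: str, b: str) -> DistanceEstimate:
    pd = p_distance(a, b)
    return DistanceEstimate(jc69_from_p(pd.value), "jc69", pd.sites_used)


def k80_from_pq(P: float, Q: float) -> float:
    """K80 distance from transition (P) and transversion (Q) proportions."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"P = {P:.4f}, Q = {Q:.4f} outside the K80 domain (saturated)"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k80_distance(a: str, b: str) -> DistanceEstimate:
    usable, ts, tv = _usable_counts(a, b)
    if usable == 0:
        raise ValueError("no usable sites (all gapped or ambiguous)")
    return DistanceEstimate(k80_from_pq(ts / usable, tv / usable), "k80", usable)


_PAIRWISE = {"p": p_distance, "jc69": jc69_distance, "k80": k80_distance}


def pairwise_distance(a: str, b: str, model: str) -> DistanceEstimate:
    if model not in _PAIRWISE:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    return _PAIRWISE[model](a, b)


def distance_matrix(aln, model: str = "k80") -> DistanceMatrix:
    """All pairwise model distances over the rows of an alignment."""
    labels = aln.species
    if len(labels) < 2:
        raise ValueError("need at least two species")
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = pairwise_distance(aln.rows[labels[i]], aln.rows[labels[j]], model)
            except SaturationError as exc:
                raise SaturationError(
                    f"pair ({labels[i]}, {labels[j]}): {exc}"
                ) from exc
            values[i, j] = values[j, i] = d.value
    return DistanceMatrix(labels, values)


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree (Saitou–Nei) as a Newick string."""
    if len(dm.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tree = _skbio_nj(_SkbioDM(dm.values, ids=dm.labels))
    return str(tree).strip()


def write_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    """Square PHYLIP distance-matrix format."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.labels)}\n")
        for label, row in zip(dm.labels, dm.values):
            fh.write(label.ljust(10) + "  ".join(f"{x:.6f}" for x in row) + "\n")
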