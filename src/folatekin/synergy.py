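"""Synergism quotients for drug combinations, classification and clustering.

The synergism quotient (SQ) of a drug pair is the combined growth-inhibition
percentage divided by the sum of the single-agent percentages:

    SQ = inh_combined / (inh_a + inh_b)

SQ > 1.1 marks synergism, 0.9 <= SQ <= 1.1 additivity and SQ < 0.9
antagonism.  For hierarchical clustering of a combinations x cell-lines SQ
matrix, a class-separating transform subtracts 10 from antagonistic values
(SQ < 0.9) and adds 10 to synergistic ones (SQ >= 1.1), so that class
membership dominates Euclidean distances; the dendrogram uses complete
linkage.

Note the two printed rules disagree at exactly SQ = 1.1: classification uses
the closed additive band [0.9, 1.1], the transform adds 10 at >= 1.1.  Both
are honored as stated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import pdist

from .errors import InputError

__all__ = [
    "CombinationRecord",
    "SQMatrix",
    "SQClusterResult",
    "synergism_quotient",
    "classify_sq",
    "transform_for_clustering",
    "cluster_sq",
    "SYNERGY_THRESHOLD",
    "ANTAGONISM_THRESHOLD",
]

SYNERGY_THRESHOLD: float = 1.1
ANTAGONISM_THRESHOLD: float = 0.9
_SHIFT: float = 10.0

InteractionClass = Literal["synergism", "additivity", "antagonism"]


@dataclass(frozen=True)
class CombinationRecord:
    """Single-agent and combined growth-inhibition percentages for one pair."""

    drug_a: str
    drug_b: str
    inhibition_a: float
    inhibition_b: float
    inhibition_combined: float
    dose_a: float | None = None
    dose_b: float | None = None
    cell_line: str = ""

    def __post_init__(self) -> None:
        for name in ("inhibition_a", "inhibition_b", "inhibition_combined"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise InputError(f"{name} must lie in [0, 100], got {v}")


@dataclass
class SQMatrix:
    """SQ values arranged combinations (rows) x cell lines (columns)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise InputError("SQ matrix must be complete (no missing values)")
        if (self.values <= 0).any().any():
            raise InputError("SQ values must be > 0")


@dataclass
class SQClusterResult:
    """Row clustering of an SQ matrix.

    ``linkage_matrix`` is the scipy condensed linkage array; ``leaf_order``
    the row labels in dendrogram order; ``newick`` the tree with merge
    heights as branch lengths.
    """

    linkage_matrix: np.ndarray
    leaf_order: list[str]
    newick: str
    transformed: pd.DataFrame


def synergism_quotient(rec: CombinationRecord) -> float:
    """SQ = combined effect over the sum of the single-agent effects."""
    denom = rec.inhibition_a + rec.inhibition_b
    if denom <= 0:
        raise InputError(
            "SQ undefined: single-agent inhibitions sum to zero "
            f"({rec.drug_a} + {rec.drug_b}, cell line {rec.cell_line!r})"
        )
    return rec.inhibition_combined / denom


def classify_sq(sq: float) -> InteractionClass:
    """Classify an SQ: >1.1 synergism, [0.9, 1.1] additivity, <0.9 antagonism."""
    if sq <= 0:
        raise InputError(f"SQ must be > 0, got {sq}")
    if sq > SYNERGY_THRESHOLD:
        return "synergism"
    if sq < ANTAGONISM_THRESHOLD:
        return "antagonism"
    return "additivity"


def transform_for_clustering(sq: float) -> float:
    """Class-separating shift: -10 below 0.9, +10 at or above 1.1."""
    if sq <= 0:
        raise InputError(f"SQ must be > 0, got {sq}")
    if sq < ANTAGONISM_THRESHOLD:
        return sq - _SHIFT
    if sq >= SYNERGY_THRESHOLD:
        return sq + _SHIFT
    return sq


def _to_newick(node, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.left, labels)
    right = _to_newick(node.right, labels)
    dl = node.dist - node.left.dist
    dr = node.dist - node.right.dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def cluster_sq(matrix: SQMatrix, transform: bool = True) -> SQClusterResult:
    """Complete-linkage Euclidean clustering of the SQ matrix rows.

    Rows are the drug combinations, the feature vector per row is the SQ
    across cell lines, shifted by :func:`transform_for_clustering` unless
    ``transform=False``.  Output is deterministic for a fixed input order;
    permuting rows permutes labels without changing tree topology.
    """
    df = matrix.values
    if len(df) < 2:
        raise InputError("clustering needs at least 2 rows")
    data = df.map(transform_for_clustering) if transform else df.astype(float)
    z = linkage(pdist(data.to_numpy(float), metric="euclidean"), method="complete")
    labels = [str(x) for x in df.index]
    order = [labels[i] for i in leaves_list(z)]
    tree = to_tree(z)
    newick = _to_newick(tree, labels) + ";"
    return SQClusterResult(
        linkage_matrix=z, leaf_order=order, newick=newick, transformed=data
    )
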