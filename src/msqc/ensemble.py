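"""Per-feature binarization and the bipartite spectrum-group graph.

Each of the m features splits the n spectra into two classes (1 = high
quality, 2 = poor quality) by ranking: the spectra in the top p% of the
feature's values are called high quality. The m binary assessments define
a bipartite graph between spectra and v = 2m group nodes, ordered
(feature 1/class 1, feature 1/class 2, feature 2/class 1, ...). Its n x v
incidence matrix A has exactly m ones per row (one group per feature), and
the v x 2 matrix Y records each group's initial class label (one 1 per row).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

N_CLASSES = 2


@dataclass(frozen=True)
class GroupNode:
    """One group node: the spectra a given feature placed in a given class."""

    index: int          # 0-based column in A
    feature_index: int  # 0-based feature
    class_index: int    # 1 = high quality, 2 = poor quality


@dataclass(frozen=True)
class EnsembleGraph:
    """Bipartite spectrum-group graph: incidence A (n x v), labels Y (v x k)."""

    A: np.ndarray
    Y: np.ndarray
    groups: tuple[GroupNode, ...]

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def v(self) -> int:
        return self.A.shape[1]

    @property
    def k(self) -> int:
        return self.Y.shape[1]

    @property
    def m(self) -> int:
        return self.v // self.k

    def validate(self) -> None:
        """Assert the structural invariants: row sums m (A) and 1 (Y)."""
        if self.A.shape[1] != self.Y.shape[0]:
            raise ValueError("A and Y have incompatible shapes")
        if not np.isin(self.A, (0, 1)).all() or not np.isin(self.Y, (0, 1)).all():
            raise ValueError("A and Y must be binary")
        if not (self.A.sum(axis=1) == self.m).all():
            raise ValueError("every spectrum must belong to exactly one group per feature")
        if not (self.Y.sum(axis=1) == 1).all():
            raise ValueError("every group must carry exactly one initial class label")


def assign_by_percentile(values, p: float = 50.0) -> np.ndarray:
    """Class labels in {1, 2}: top p% of values (descending) get class 1.

    Exactly ``ceil(n * p / 100)`` spectra are assigned class 1. Ties at the
    boundary break by input position (stable descending sort), so the
    assignment is deterministic for a fixed input order.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        raise ValueError("cannot binarize an empty value sequence")
    if not 0 < p < 100:
        raise ValueError(f"percentile must be in (0, 100), got {p}")
    n_high = math.ceil(n * p / 100.0)
    order = np.argsort(-values, kind="stable")
    classes = np.full(n, 2, dtype=int)
    classes[order[:n_high]] = 1
    return classes


def binarize_features(feature_matrix, p: float = 50.0) -> np.ndarray:
    """Apply :func:`assign_by_percentile` column-wise to an n x m table."""
    X = np.asarray(feature_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-dimensional")
    return np.column_stack([assign_by_percentile(X[:, j], p)
                            for j in range(X.shape[1])])


def build_graph(assignments) -> EnsembleGraph:
    """Build the bipartite graph from an n x m table of class labels in {1, 2}."""
    asg = np.asarray(assignments)
    if asg.ndim != 2:
        raise ValueError("assignments must be an n x m table")
    if not np.isin(asg, (1, 2)).all():
        raise ValueError("assignments must take values in {1, 2}")
    n, m = asg.shape
    v = N_CLASSES * m
    A = np.zeros((n, v), dtype=np.int8)
    cols = N_CLASSES * np.arange(m) + (asg - 1)
    A[np.arange(n)[:, None], cols] = 1
    groups = tuple(
        GroupNode(index=N_CLASSES * f + (z - 1), feature_index=f, class_index=z)
        for f in range(m) for z in range(1, N_CLASSES + 1)
    )
    Y = np.zeros((v, N_CLASSES), dtype=np.int8)
    for g in groups:
        Y[g.index, g.class_index - 1] = 1
    graph = EnsembleGraph(A=A, Y=Y, groups=groups)
    graph.validate()
    return graph
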