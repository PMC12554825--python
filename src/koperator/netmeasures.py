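"""Thresholding, sparsity, modularity and asymmetry of brain matrices.

Sparsity is the fraction of zero entries (after an optional threshold),
modularity is Newman's Q for a non-negative weighted graph, and asymmetry
is the relative Frobenius norm of the antisymmetric part — zero exactly
when the matrix is symmetric.  Connectivity matrices carry signed weights,
so modularity works on a shifted copy (entries + shift >= 0); the pipeline
defaults follow the convention of +1 for connectivity matrices and +1000
for ratio-K matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .matrices import SquareMatrix

__all__ = [
    "MeasureReport",
    "apply_threshold",
    "sparsity",
    "modularity",
    "modularity_q",
    "asymmetry",
    "measure_report",
]


def apply_threshold(
    a: SquareMatrix, tau: float, mode: str = "absolute"
) -> SquareMatrix:
    """Zero out weak entries: |a_ij| < tau (absolute) or a_ij < tau (signed).

    The diagonal is treated like any other entry.
    """
    if mode == "absolute":
        if tau < 0:
            raise ValueError("tau must be >= 0 in absolute mode")
        kept = np.abs(a.values) >= tau
    elif mode == "signed":
        kept = a.values >= tau
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    return SquareMatrix(values=np.where(kept, a.values, 0.0), labels=a.labels)


def sparsity(a: SquareMatrix) -> float:
    """Fraction of zero entries: 1 - |{(i,j): a_ij != 0}| / (n * m)."""
    v = a.values
    return 1.0 - np.count_nonzero(v) / v.size


def modularity_q(
    values: np.ndarray, communities: np.ndarray
) -> float:
    """Newman's Q on a non-negative weighted adjacency grid.

    Q = (1/2m) * sum_ij [A_ij - k_i k_j / 2m] * delta(c_i, c_j)
    with 2m the total weight sum and k_i the weighted degree of node i.
    """
    a = np.asarray(values, dtype=float)
    two_m = a.sum()
    if two_m <= 0:
        raise ValueError("total edge weight must be positive")
    k = a.sum(axis=1)
    same = communities[:, None] == communities[None, :]
    return float(np.sum((a - np.outer(k, k) / two_m) * same) / two_m)


def _find_partition(values: np.ndarray) -> dict[int, int]:
    """Greedy modularity maximisation (Clauset-Newman-Moore) on the weighted
    graph; ties resolved deterministically, singleton fallback for edgeless
    graphs."""
    n = values.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(values))
    for i, j in zip(ii.tolist(), jj.tolist()):
        if i != j:
            g.add_edge(i, j, weight=float(values[i, j]))
    if g.number_of_edges() == 0:
        return {i: i for i in range(n)}
    comms = nx.community.greedy_modularity_communities(g, weight="weight")
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    return {node: ci for ci, c in enumerate(comms) for node in c}


def modularity(
    a: SquareMatrix,
    shift: float = 0.0,
    partition: dict[str, int] | None = None,
) -> tuple[float, dict[str, int]]:
    """Newman modularity of ``a`` after adding ``shift`` to every entry.

    If no partition is given, one is found by greedy modularity maximisation
    on the shifted matrix.  Returns (Q, partition by label).  All shifted
    entries must be non-negative.
    """
    shifted = a.values + shift
    if np.min(shifted) < 0:
        raise ValueError(
            f"shifted matrix still has negative entries (min "
            f"{np.min(shifted):.4g}); use a shift >= {-np.min(a.values):.4g}"
        )
    if partition is None:
        by_index = _find_partition(shifted)
        partition = {a.labels[i]: c for i, c in by_index.items()}
    else:
        missing = set(a.labels) - set(partition)
        if missing:
            raise ValueError(f"partition missing labels: {sorted(missing)}")
    communities = np.array([partition[lab] for lab in a.labels])
    return modularity_q(shifted, communities), dict(partition)


def asymmetry(a: SquareMatrix) -> float:
    """Relative antisymmetry ||A - A^T||_F / ||A||_F.

    Zero iff A is symmetric; invariant under global positive rescaling.
    """
    norm = np.linalg.norm(a.values)
    if norm == 0:
        raise ValueError("asymmetry is undefined for the zero matrix")
    return float(np.linalg.norm(a.values - a.values.T) / norm)


@dataclass(frozen=True)
class MeasureReport:
    """Sparsity / modularity / asymmetry summary of one matrix."""

    sparsity: float
    modularity: float
    asymmetry: float
    threshold_used: float
    shift_used: float
    partition: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "sparsity": self.sparsity,
            "modularity": self.modularity,
            "asymmetry": self.asymmetry,
            "threshold_used": self.threshold_used,
            "shift_used": self.shift_used,
            "partition": self.partition,
        }


def measure_report(
    a: SquareMatrix,
    tau: float = 0.3,
    shift: float = 0.0,
    threshold_mode: str = "absolute",
) -> MeasureReport:
    """Threshold, then measure: sparsity of the thresholded matrix,
    modularity of the thresholded-and-shifted matrix, asymmetry of the
    original."""
    thresholded = apply_threshold(a, tau, mode=threshold_mode)
    q, partition = modularity(thresholded, shift=shift)
    return MeasureReport(
        sparsity=sparsity(thresholded),
        modularity=q,
        asymmetry=asymmetry(a),
        threshold_used=tau,
        shift_used=shift,
        partition=partition,
    )
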