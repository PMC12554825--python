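"""The K-operator: four ways to quantify change between two brain matrices.

Given a reference connectivity matrix G and a later, disease-altered matrix
G^k (the superscript k is a label, not a power), the K-operator is the matrix
that maps one onto the other, K G = G^k.  Four constructions are provided:

- ``k_matrix_product`` — K^@ = G^k @ G^{-1}, the row-by-column (formally
  justified) form: applying K^@ to G by matrix product recovers G^k exactly.
- ``k_mixed``          — K^* = G^k * G^{-1}, the Hadamard (element-wise)
  product with the inverse: symmetric for symmetric inputs and easier to
  read connection-by-connection.
- ``k_ratio``          — K_ij = G^k_ij / G_ij, the exact element-wise form
  used for successive time points; zero denominators are replaced by a
  small floor rather than raising.
- ``k_kernel``         — a Gaussian-kernel similarity between the rows of
  the two matrices; experimental, entries in (0, 1].

``t_matrix`` returns T = K^@ - K^*, the exact correction relating the two
inverse-based forms; treating T as a perturbation yields the first-order
eigenvalue shift implemented in :mod:`koperator.spectral`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrices import DEFAULT_MAX_CONDITION, SquareMatrix, invert

__all__ = [
    "KMatrix",
    "TMatrix",
    "k_matrix_product",
    "k_mixed",
    "k_ratio",
    "k_kernel",
    "t_matrix",
    "median_row_bandwidth",
]

K_METHODS = ("matrix_product", "mixed", "ratio", "kernel")

DEFAULT_ZERO_FLOOR = 1e-6


@dataclass(frozen=True)
class KMatrix(SquareMatrix):
    """A K-operator tagged with the product method that produced it."""

    method: str = "ratio"
    from_tag: str = ""
    to_tag: str = ""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.method not in K_METHODS:
            raise ValueError(f"unknown K method {self.method!r}; one of {K_METHODS}")


@dataclass(frozen=True)
class TMatrix(SquareMatrix):
    """Difference between the row-by-column and mixed K forms: K^@ = K^* + T."""


def _check_pair(gk: SquareMatrix, g: SquareMatrix) -> None:
    gk.require_same_labels(g)
    if gk.values.shape != g.values.shape:
        raise ValueError("matrices must have the same shape")


def k_matrix_product(
    gk: SquareMatrix,
    g: SquareMatrix,
    max_condition: float = DEFAULT_MAX_CONDITION,
) -> KMatrix:
    """Row-by-column K: K^@ = G^k @ G^{-1}.

    Exact in the sense that K^@ @ G reproduces G^k to numerical precision.
    Generally asymmetric even for symmetric inputs.
    """
    _check_pair(gk, g)
    inv = invert(g, max_condition=max_condition)
    return KMatrix(
        values=gk.values @ inv.values,
        labels=gk.labels,
        method="matrix_product",
        from_tag=getattr(g, "source_tag", ""),
        to_tag=getattr(gk, "source_tag", ""),
    )


def k_mixed(
    gk: SquareMatrix,
    g: SquareMatrix,
    max_condition: float = DEFAULT_MAX_CONDITION,
) -> KMatrix:
    """Mixed K: K^* = G^k * G^{-1} element-wise (Hadamard with the inverse).

    Symmetric whenever both inputs are symmetric, which makes the damaged
    connections directly readable pair-by-pair.
    """
    _check_pair(gk, g)
    inv = invert(g, max_condition=max_condition)
    return KMatrix(
        values=gk.values * inv.values,
        labels=gk.labels,
        method="mixed",
        from_tag=getattr(g, "source_tag", ""),
        to_tag=getattr(gk, "source_tag", ""),
    )


def k_ratio(
    gk_next: SquareMatrix,
    gk_prev: SquareMatrix,
    zero_floor: float = DEFAULT_ZERO_FLOOR,
) -> KMatrix:
    """Element-wise ratio K: K_ij = G(t+1)_ij / G(t)_ij.

    Denominators smaller in magnitude than ``zero_floor`` are replaced by
    ``zero_floor`` carrying the denominator's sign (positive when the entry
    is exactly zero), so no division by zero can occur.  No matrix inversion
    is needed, and K from identical inputs is the all-ones matrix.
    """
    _check_pair(gk_next, gk_prev)
    if zero_floor <= 0:
        raise ValueError("zero_floor must be positive")
    prev = gk_prev.values
    sign = np.where(prev < 0, -1.0, 1.0)  # zero gets the positive sign
    denom = sign * np.maximum(np.abs(prev), zero_floor)
    return KMatrix(
        values=gk_next.values / denom,
        labels=gk_next.labels,
        method="ratio",
        from_tag=getattr(gk_prev, "source_tag", ""),
        to_tag=getattr(gk_next, "source_tag", ""),
    )


def median_row_bandwidth(gk: SquareMatrix, g: SquareMatrix) -> float:
    """Median heuristic: median pairwise distance between rows of gk and g."""
    d = np.sqrt(
        np.sum((gk.values[:, None, :] - g.values[None, :, :]) ** 2, axis=-1)
    )
    positive = d[d > 0]
    if positive.size == 0:
        return 1.0
    return float(np.median(positive))


def k_kernel(
    gk: SquareMatrix,
    g: SquareMatrix,
    bandwidth: float | None = None,
) -> KMatrix:
    """Gaussian-kernel K (experimental): row-similarity between G^k and G.

    K_ij = exp(-||row_i(G^k) - row_j(G)||^2 / (2 bandwidth^2)); entries lie
    in (0, 1].  The default bandwidth is the median pairwise row distance.
    Unlike the other forms this measures similarity, not change, and is
    generally asymmetric.
    """
    if gk.values.shape != g.values.shape:
        raise ValueError("matrices must have the same shape")
    if bandwidth is None:
        bandwidth = median_row_bandwidth(gk, g)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    sq = np.sum((gk.values[:, None, :] - g.values[None, :, :]) ** 2, axis=-1)
    return KMatrix(
        values=np.exp(-sq / (2.0 * bandwidth**2)),
        labels=gk.labels if gk.labels == g.labels else gk.labels,
        method="kernel",
        from_tag=getattr(g, "source_tag", ""),
        to_tag=getattr(gk, "source_tag", ""),
    )


def t_matrix(
    gk: SquareMatrix,
    g: SquareMatrix,
    max_condition: float = DEFAULT_MAX_CONDITION,
) -> TMatrix:
    """T = K^@ - K^*, exact to floating-point roundoff by construction."""
    ka = k_matrix_product(gk, g, max_condition=max_condition)
    ks = k_mixed(gk, g, max_condition=max_condition)
    return TMatrix(values=ka.values - ks.values, labels=gk.labels)
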