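"""Eigen-decomposition, 2x2 closed forms, and spectrum comparison.

The eigenvalue spectrum is the main lens used to compare K-operators built
with different products: similar spectra across constructions ("spectral
similarity") suggest the constructions capture the same disease action.
For the 2x2 case, writing K^@ = K^* + T and expanding the characteristic
polynomial gives a closed form; dropping terms that are second order in the
entries of T leaves the eigenvalues of K^* shifted by (T_11 + T_22)/2 — a
first-order perturbation result.
"""

from __future__ import annotations

import cmath
from dataclasses import dataclass

import numpy as np

from .matrices import SquareMatrix

__all__ = [
    "Spectrum",
    "SimilarityReport",
    "eigen_spectrum",
    "eigen_2x2_closed_form",
    "eigen_approx_first_order",
    "spectral_similarity",
]

ORDER_RULES = ("real_desc", "magnitude_desc", "none")

_SYM_TOL = 1e-12


def _order(eigvals: np.ndarray, eigvecs: np.ndarray | None, rule: str):
    if rule == "real_desc":
        idx = np.lexsort((-eigvals.imag, -eigvals.real))
    elif rule == "magnitude_desc":
        idx = np.argsort(-np.abs(eigvals), kind="stable")
    elif rule == "none":
        return eigvals, eigvecs
    else:
        raise ValueError(f"unknown order rule {rule!r}; one of {ORDER_RULES}")
    return eigvals[idx], (eigvecs[:, idx] if eigvecs is not None else None)


@dataclass(frozen=True)
class Spectrum:
    """Ordered complex eigenvalues, optionally with paired eigenvectors."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray | None = None
    order_rule: str = "real_desc"

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=complex)
        object.__setattr__(self, "eigenvalues", ev)
        if self.order_rule not in ORDER_RULES:
            raise ValueError(f"unknown order rule {self.order_rule!r}")

    def __len__(self) -> int:
        return len(self.eigenvalues)

    @property
    def real_parts(self) -> np.ndarray:
        return self.eigenvalues.real


def eigen_spectrum(
    m: SquareMatrix | np.ndarray,
    order_rule: str = "real_desc",
    compute_vectors: bool = True,
) -> Spectrum:
    """Full eigen-decomposition with a chosen eigenvalue ordering.

    Symmetric input is routed through the symmetric solver, so its spectrum
    comes back exactly real.
    """
    a = m.values if isinstance(m, SquareMatrix) else np.asarray(m, dtype=float)
    if np.max(np.abs(a - a.T)) <= _SYM_TOL:
        w, v = np.linalg.eigh(a)
        w = w.astype(complex)
        v = v.astype(complex)
    else:
        w, v = np.linalg.eig(a)
    w, v = _order(w, v, order_rule)
    return Spectrum(
        eigenvalues=w,
        eigenvectors=v if compute_vectors else None,
        order_rule=order_rule,
    )


def eigen_2x2_closed_form(
    a: float, b: float, c: float, d: float,
    e: float, f: float, g: float, h: float,
) -> tuple[complex, complex]:
    """Exact eigenvalues of [[a,b],[c,d]] + [[e,f],[g,h]].

    Closed form from the characteristic polynomial of the 2x2 sum K^* + T:
    lambda_{1,2} = ( (a+d+e+h) -/+ sqrt((-a-d-e-h)^2
                     - 4 (ad + ah - bc - bg - cf + de + eh - fg)) ) / 2.
    A negative discriminant yields a complex-conjugate pair.
    """
    trace = a + d + e + h
    disc = (-a - d - e - h) ** 2 - 4.0 * (
        a * d + a * h - b * c - b * g - c * f + d * e + e * h - f * g
    )
    root = cmath.sqrt(disc)
    lam1 = 0.5 * (trace - root)
    lam2 = 0.5 * (trace + root)
    return lam1, lam2


def eigen_approx_first_order(
    a: float, b: float, c: float, d: float, e: float, h: float
) -> tuple[complex, complex]:
    """First-order eigenvalues of K^* + T: exact 2x2 spectrum of [[a,b],[c,d]]
    shifted by (e + h)/2.

    Neglects terms of second order in the perturbation T, keeping only its
    diagonal mean; the off-diagonal entries of T drop out entirely at this
    order.  The approximation error vanishes linearly (or faster) as T is
    scaled to zero.
    """
    trace = a + d
    disc = (-a - d) ** 2 - 4.0 * (a * d - b * c)
    root = cmath.sqrt(disc)
    shift = 0.5 * (e + h)
    lam1 = 0.5 * (trace - root) + shift
    lam2 = 0.5 * (trace + root) + shift
    return lam1, lam2


@dataclass(frozen=True)
class SimilarityReport:
    """L2 distance and Pearson correlation of two sorted real spectra."""

    l2_distance: float
    pearson_correlation: float
    n: int


def spectral_similarity(s1: Spectrum, s2: Spectrum) -> SimilarityReport:
    """Compare two spectra through their sorted real parts.

    Distance 0 iff the sorted real parts coincide; the correlation is NaN
    when either sorted spectrum is constant (zero variance).
    """
    if len(s1) != len(s2):
        raise ValueError(f"spectrum lengths differ: {len(s1)} vs {len(s2)}")
    r1 = np.sort(s1.real_parts)
    r2 = np.sort(s2.real_parts)
    dist = float(np.linalg.norm(r1 - r2))
    if r1.std() == 0.0 or r2.std() == 0.0:
        corr = float("nan")
    else:
        corr = float(np.corrcoef(r1, r2)[0, 1])
        corr = float(np.clip(corr, -1.0, 1.0))
    return SimilarityReport(l2_distance=dist, pearson_correlation=corr, n=len(s1))
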