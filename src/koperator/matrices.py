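"""Core square-matrix types, synthetic generators and delimited-text I/O.

Connectivity matrices of the brain functional network are real n x n grids
whose rows and columns are regions of interest (ROIs).  Everything downstream
(the K-operator, spectra, network measures) works on these containers, so the
invariants are enforced at construction time: finite entries, unique labels,
and — for connectivity matrices — symmetry, unit diagonal and entries in
[-1, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import block_diag

__all__ = [
    "SquareMatrix",
    "ConnectivityMatrix",
    "InverseMatrix",
    "SingularMatrixError",
    "invert",
    "make_block_brain",
    "make_random_symmetric",
    "make_sparse_symmetric",
    "read_matrix",
    "write_matrix",
]

DEFAULT_MAX_CONDITION = 1e12


class SingularMatrixError(np.linalg.LinAlgError):
    """Raised when a matrix is singular or too ill-conditioned to invert."""


def _default_labels(n: int) -> tuple[str, ...]:
    return tuple(f"ROI{i + 1}" for i in range(n))


@dataclass(frozen=True)
class SquareMatrix:
    """An n x n real matrix with ordered node labels.

    Labels are opaque strings; positions are 0-based.  Label order defines
    row and column order identically.
    """

    values: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"matrix must be square, got shape {values.shape}")
        if values.shape[0] < 2:
            raise ValueError("matrix must be at least 2 x 2")
        if not np.all(np.isfinite(values)):
            raise ValueError("matrix entries must all be finite")
        labels = tuple(self.labels) if self.labels else _default_labels(values.shape[0])
        if len(labels) != values.shape[0]:
            raise ValueError(
                f"{len(labels)} labels for a {values.shape[0]} x {values.shape[0]} matrix"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("labels must be unique")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown label {label!r}") from None

    def same_labels(self, other: "SquareMatrix") -> bool:
        return self.labels == other.labels

    def require_same_labels(self, other: "SquareMatrix") -> None:
        if not self.same_labels(other):
            raise ValueError("matrices have mismatched labels or label order")


@dataclass(frozen=True)
class ConnectivityMatrix(SquareMatrix):
    """Symmetric unit-diagonal matrix of pairwise ROI correlations in [-1, 1]."""

    source_tag: str = ""

    _SYM_TOL = 1e-10

    def __post_init__(self) -> None:
        super().__post_init__()
        v = self.values
        if np.max(np.abs(v - v.T)) > self._SYM_TOL:
            raise ValueError("connectivity matrix must be symmetric (tol 1e-10)")
        if not np.all(np.diag(v) == 1.0):
            raise ValueError("connectivity matrix diagonal must equal 1 exactly")
        if np.min(v) < -1.0 or np.max(v) > 1.0:
            raise ValueError("connectivity entries must lie in [-1, 1]")


@dataclass(frozen=True)
class InverseMatrix(SquareMatrix):
    """Inverse of a source matrix, carrying its condition-number estimate."""

    condition_estimate: float = float("nan")


def invert(
    g: SquareMatrix, max_condition: float = DEFAULT_MAX_CONDITION
) -> InverseMatrix:
    """Invert ``g``, failing loudly on singular or ill-conditioned input.

    No regularisation is applied: the operator algebra assumes non-singular
    connectivity matrices, and a silent pseudo-inverse would corrupt the
    downstream K-operators.

    Raises
    ------
    SingularMatrixError
        If the 2-norm condition estimate exceeds ``max_condition`` or the
        matrix is exactly singular.
    """
    cond = float(np.linalg.cond(g.values))
    if not np.isfinite(cond) or cond > max_condition:
        raise SingularMatrixError(
            f"matrix is singular or ill-conditioned: condition estimate "
            f"{cond:.3e} exceeds limit {max_condition:.3e}"
        )
    inv = np.linalg.inv(g.values)
    return InverseMatrix(values=inv, labels=g.labels, condition_estimate=cond)


def make_block_brain(blocks: Sequence[SquareMatrix]) -> SquareMatrix:
    """Assemble a block-diagonal brain matrix from per-lobe blocks.

    Each diagonal block holds the intra-lobe connections; all inter-lobe
    entries are zero.  The spectrum of the result is the multiset union of
    the block spectra.  Blocks must be square, symmetric and unit-diagonal.
    Labels are concatenated; on collision they are prefixed ``b{i}:``.
    """
    if len(blocks) == 0:
        raise ValueError("at least one block is required")
    for i, b in enumerate(blocks):
        v = b.values
        if np.max(np.abs(v - v.T)) > 1e-10:
            raise ValueError(f"block {i} is not symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError(f"block {i} does not have a unit diagonal")
    if len(blocks) == 1:
        return blocks[0]
    flat = [lab for b in blocks for lab in b.labels]
    if len(set(flat)) == len(flat):
        labels = tuple(flat)
    else:
        labels = tuple(f"b{i}:{lab}" for i, b in enumerate(blocks) for lab in b.labels)
    values = block_diag(*[b.values for b in blocks])
    return SquareMatrix(values=values, labels=labels)


def make_random_symmetric(
    n: int,
    value_range: tuple[float, float] = (0.0, 1.0),
    unit_diagonal: bool = True,
    seed: int | None = None,
) -> SquareMatrix:
    """Random symmetric matrix with i.i.d. uniform off-diagonal entries.

    With ``unit_diagonal`` and ``value_range`` inside [-1, 1] this emulates
    the statistical shape of a functional connectome.
    """
    lo, hi = value_range
    if lo > hi:
        raise ValueError(f"degenerate value range ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = rng.uniform(lo, hi, size=len(iu[0]))
    m = m + m.T
    if unit_diagonal:
        np.fill_diagonal(m, 1.0)
    else:
        np.fill_diagonal(m, rng.uniform(lo, hi, size=n))
    return SquareMatrix(values=m)


def make_sparse_symmetric(
    n: int,
    density: float,
    sigma: float = 0.01,
    seed: int | None = None,
) -> SquareMatrix:
    """Sparse symmetric matrix with uniform(0,1) non-zeros perturbed by noise.

    ``density`` is the expected fraction of non-zero off-diagonal entries;
    non-zero values are uniform(0, 1) plus additive uniform(-sigma, sigma)
    noise, clipped to [0, 1].  The diagonal is set to 1 so the matrix stays
    invertible for the operator computations.  sigma is meant to be << 1.
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError(f"density must be in [0, 1], got {density}")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if density == 0.0:
        warnings.warn(
            "density 0 produces an off-diagonally empty matrix; downstream "
            "inversion of fully sparse matrices can be degenerate",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    k = len(iu[0])
    mask = rng.random(k) < density
    vals = rng.uniform(0.0, 1.0, size=k) + rng.uniform(-sigma, sigma, size=k)
    m[iu] = np.where(mask, np.clip(vals, 0.0, 1.0), 0.0)
    m = m + m.T
    np.fill_diagonal(m, 1.0)
    return SquareMatrix(values=m)


# ---------------------------------------------------------------------------
# File I/O: delimited text with a header row of labels (CSV/TSV sniffed by
# extension), or a .npy array with a companion .labels.json.


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def write_matrix(m: SquareMatrix, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, m.values)
        side = path.with_suffix(".labels.json")
        side.write_text(json.dumps(list(m.labels)))
        return path
    df = pd.DataFrame(m.values, columns=list(m.labels))
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")
    return path


def read_matrix(path: str | Path) -> SquareMatrix:
    path = Path(path)
    if path.suffix == ".npy":
        values = np.load(path)
        side = path.with_suffix(".labels.json")
        labels = tuple(json.loads(side.read_text())) if side.exists() else ()
        return SquareMatrix(values=values, labels=labels)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"could not parse matrix file {path}: {exc}") from exc
    if df.isnull().any().any():
        raise ValueError(f"matrix file {path} has missing or ragged cells")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"matrix file {path} contains non-numeric cells")
    if values.shape[0] != values.shape[1]:
        raise ValueError(
            f"matrix file {path} is not square: {values.shape[0]} rows, "
            f"{values.shape[1]} columns"
        )
    return SquareMatrix(values=values, labels=tuple(str(c) for c in df.columns))
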