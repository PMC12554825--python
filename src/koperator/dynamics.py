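"""Synthetic brain dynamics and the time-evolving ratio K-operator.

Four models emulate the time evolution of a diseased brain as a sequence of
symmetric matrices with entries in (0, 1):

- ``null``        — every time point is an independent uniform(0,1) draw;
- ``increasing``  — each step adds a fresh per-entry increment drawn
  uniformly from ``delta_range`` (default (0.01, 0.05));
- ``decreasing``  — each step subtracts such an increment; initial entries
  are drawn from uniform(0.55, 1) so nine max-0.05 decrements stay positive;
- ``varying``     — increases up to the midpoint step, then decreases.

The stepwise ratio operator K(t) = G(t+1) / G(t) (element-wise) separates
the models by its range: every element is >= 1 for the increasing model,
in (0, 1) for the decreasing one, and crosses 1 at the midpoint for the
varying one, while the null model respects no such band.  Least-squares
linear and quadratic fits of per-element trajectories provide the
continuous-time description.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .matrices import SquareMatrix
from .operators import DEFAULT_ZERO_FLOOR, KMatrix, k_ratio

__all__ = [
    "DynamicsSeries",
    "KTrajectory",
    "RegressionFit",
    "MODELS",
    "simulate_model",
    "evolve_k",
    "classify_dynamics",
    "fit_linear",
    "fit_quadratic",
    "select_roi_pairs",
    "extract_pair_series",
]

MODELS = ("null", "increasing", "decreasing", "varying")


@dataclass(frozen=True)
class DynamicsSeries:
    """An ordered sequence of same-shape matrices indexed by time."""

    matrices: tuple[SquareMatrix, ...]
    time_labels: tuple[float, ...] = ()
    model_tag: str = ""

    def __post_init__(self) -> None:
        mats = tuple(self.matrices)
        if len(mats) < 2:
            raise ValueError("a dynamics series needs at least 2 matrices")
        first = mats[0]
        for m in mats[1:]:
            if m.values.shape != first.values.shape or m.labels != first.labels:
                raise ValueError("all matrices must share shape and labels")
        times = (
            tuple(self.time_labels)
            if self.time_labels
            else tuple(float(t) for t in range(1, len(mats) + 1))
        )
        if len(times) != len(mats):
            raise ValueError("time label count does not match matrix count")
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("time labels must be strictly increasing")
        object.__setattr__(self, "matrices", mats)
        object.__setattr__(self, "time_labels", times)

    def __len__(self) -> int:
        return len(self.matrices)

    @property
    def labels(self) -> tuple[str, ...]:
        return self.matrices[0].labels

    def stack(self) -> np.ndarray:
        """steps x n x n array of the matrix values."""
        return np.stack([m.values for m in self.matrices])


@dataclass(frozen=True)
class KTrajectory:
    """Step-wise ratio K matrices of a dynamics series, with element ranges."""

    k_matrices: tuple[KMatrix, ...]
    element_range: tuple[float, float]

    def __len__(self) -> int:
        return len(self.k_matrices)

    def step_means(self) -> np.ndarray:
        return np.array([m.values.mean() for m in self.k_matrices])


def simulate_model(
    model: str,
    n: int = 4,
    steps: int = 10,
    delta_range: tuple[float, float] = (0.01, 0.05),
    seed: int | None = None,
    init_range: tuple[float, float] | None = None,
) -> DynamicsSeries:
    """Generate a seeded sequence of symmetric matrices under one model.

    Increments are drawn independently per entry and per step and mirrored
    across the diagonal so every matrix stays symmetric.  Increasing-model
    entries are not clipped at 1.  For the decreasing and varying models the
    initial range must survive the worst-case run of decrements; violating
    parameters raise rather than silently go negative.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; one of {MODELS}")
    if steps < 2:
        raise ValueError("steps must be >= 2")
    lo, hi = delta_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError("delta_range must satisfy 0 < lo <= hi < 1")

    if init_range is None:
        init_range = (0.55, 1.0) if model in ("decreasing", "varying") else (0.0, 1.0)
    init_lo, init_hi = init_range

    n_down = {
        "decreasing": steps - 1,
        "varying": (steps - 1) - (steps // 2),
    }.get(model, 0)
    if model in ("decreasing", "varying") and n_down * hi >= init_lo:
        raise ValueError(
            f"{model} model can reach non-positive entries: {n_down} decrements "
            f"of up to {hi} against a minimum initial value {init_lo}"
        )

    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n)  # diagonal included: every entry evolves

    def sym(draw: np.ndarray) -> np.ndarray:
        m = np.zeros((n, n))
        m[iu] = draw
        return m + np.triu(m, k=1).T

    k_up = len(iu[0])
    mats: list[np.ndarray] = []
    if model == "null":
        for _ in range(steps):
            mats.append(sym(rng.uniform(0.0, 1.0, size=k_up)))
    else:
        current = sym(rng.uniform(init_lo, init_hi, size=k_up))
        mats.append(current)
        mid = steps // 2
        for t in range(1, steps):
            delta = sym(rng.uniform(lo, hi, size=k_up))
            if model == "increasing" or (model == "varying" and t <= mid):
                current = current + delta
            else:
                current = current - delta
            mats.append(current)

    return DynamicsSeries(
        matrices=tuple(SquareMatrix(values=m) for m in mats),
        model_tag=model,
    )


def evolve_k(
    series: DynamicsSeries, zero_floor: float = DEFAULT_ZERO_FLOOR
) -> KTrajectory:
    """Step-wise ratio operators K(t) = G(t+1) / G(t) along a series."""
    ks = tuple(
        k_ratio(series.matrices[t + 1], series.matrices[t], zero_floor=zero_floor)
        for t in range(len(series) - 1)
    )
    all_vals = np.stack([k.values for k in ks])
    return KTrajectory(
        k_matrices=ks,
        element_range=(float(all_vals.min()), float(all_vals.max())),
    )


def classify_dynamics(traj: KTrajectory) -> str:
    """Label a K trajectory by the band its per-step mean elements occupy.

    All step-means > 1 -> increasing; all in (0, 1) -> decreasing; a prefix
    above 1 followed by a suffix below 1 -> varying; anything else (including
    the all-ones boundary) -> null.
    """
    means = traj.step_means()
    if np.all(means > 1.0):
        return "increasing"
    if np.all((means > 0.0) & (means < 1.0)):
        return "decreasing"
    for split in range(1, len(means)):
        if np.all(means[:split] > 1.0) and np.all(
            (means[split:] > 0.0) & (means[split:] < 1.0)
        ):
            return "varying"
    return "null"


@dataclass(frozen=True)
class RegressionFit:
    """Per-element least-squares polynomial fit of a matrix trajectory.

    ``coefficients`` has shape (degree+1, n, n), highest power first, so for
    degree 1 the model is G_ij(t) = a_ij * t + b_ij and for degree 2
    G_ij(t) = a_ij * t^2 + b_ij * t + c_ij.
    """

    degree: int
    coefficients: np.ndarray
    residual_sse: np.ndarray
    labels: tuple[str, ...]

    def predict(self, t: float | np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        powers = np.stack(
            [t ** (self.degree - p) for p in range(self.degree + 1)]
        )  # (degree+1, ...)
        return np.tensordot(powers, self.coefficients, axes=(0, 0))

    def element(self, i: int, j: int) -> np.ndarray:
        """Coefficient vector of one element, highest power first."""
        return self.coefficients[:, i, j]


def _fit(series: DynamicsSeries, degree: int) -> RegressionFit:
    t = np.asarray(series.time_labels)
    if len(t) < degree + 1:
        raise ValueError(
            f"degree-{degree} fit needs at least {degree + 1} time points, "
            f"got {len(t)}"
        )
    y = series.stack().reshape(len(t), -1)  # time x elements
    design = np.vander(t, degree + 1)  # highest power first
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    n = series.matrices[0].n
    return RegressionFit(
        degree=degree,
        coefficients=coef.reshape(degree + 1, n, n),
        residual_sse=np.sum(resid**2, axis=0).reshape(n, n),
        labels=series.labels,
    )


def fit_linear(series: DynamicsSeries) -> RegressionFit:
    """Per-element linear trend G_ij(t) = a t + b."""
    return _fit(series, degree=1)


def fit_quadratic(series: DynamicsSeries) -> RegressionFit:
    """Per-element quadratic trend G_ij(t) = a t^2 + b t + c.

    On exactly three time points this interpolates, so the residual is zero.
    """
    return _fit(series, degree=2)


def select_roi_pairs(
    k: SquareMatrix, top_n: int = 5
) -> list[tuple[str, str, float]]:
    """Rank off-diagonal ROI pairs by |K| descending.

    Symmetric duplicates are collapsed to the upper-triangle pair; ties break
    by ascending (row, col) index.  Asking for more pairs than exist returns
    all of them with a warning.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    n = k.n
    pairs = [
        (i, j, float(k.values[i, j])) for i in range(n) for j in range(i + 1, n)
    ]
    pairs.sort(key=lambda p: (-abs(p[2]), p[0], p[1]))
    if top_n > len(pairs):
        warnings.warn(
            f"requested {top_n} pairs but only {len(pairs)} exist; returning all",
            stacklevel=2,
        )
        top_n = len(pairs)
    return [(k.labels[i], k.labels[j], v) for i, j, v in pairs[:top_n]]


def extract_pair_series(
    series: DynamicsSeries, label_i: str, label_j: str
) -> DynamicsSeries:
    """Restrict a series to the 2x2 submatrices of one ROI pair.

    Each submatrix keeps the rows and columns of (label_i, label_j); for
    connectivity input its diagonal entries stay exactly 1 through time.
    """
    if label_i == label_j:
        raise ValueError("the two ROI labels must differ")
    i = series.matrices[0].index_of(label_i)
    j = series.matrices[0].index_of(label_j)
    idx = np.array([i, j])
    subs = tuple(
        SquareMatrix(
            values=m.values[np.ix_(idx, idx)], labels=(label_i, label_j)
        )
        for m in series.matrices
    )
    return DynamicsSeries(
        matrices=subs,
        time_labels=series.time_labels,
        model_tag=series.model_tag,
    )
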