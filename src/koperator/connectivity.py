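"""ROI time series, Pearson connectivity matrices, and a Gaussian fixture
generator with controllable coupling.

The connectivity matrix of a resting-state session is the n x n table of
Pearson correlations between the fMRI time series of every ROI pair.  The
synthetic generator draws multivariate-normal series with a prescribed
correlation structure, standing in for fMRI data in tests and examples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .matrices import ConnectivityMatrix

__all__ = [
    "RoiTimeSeries",
    "correlation_matrix",
    "synth_timeseries",
    "read_timeseries",
    "write_timeseries",
]


@dataclass(frozen=True)
class RoiTimeSeries:
    """T x n table of ROI signals: one row per time point, one column per ROI."""

    values: np.ndarray
    roi_labels: tuple[str, ...] = ()
    time_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("time series must be a 2-D (time x ROI) array")
        if values.shape[0] < 3:
            raise ValueError("need at least 3 time points")
        if not np.all(np.isfinite(values)):
            raise ValueError("time series contains missing or non-finite values")
        labels = (
            tuple(self.roi_labels)
            if self.roi_labels
            else tuple(f"ROI{i + 1}" for i in range(values.shape[1]))
        )
        if len(labels) != values.shape[1]:
            raise ValueError("label count does not match ROI count")
        if len(set(labels)) != len(labels):
            raise ValueError("ROI labels must be unique")
        sd = values.std(axis=0)
        if np.any(sd == 0.0):
            dead = [labels[i] for i in np.flatnonzero(sd == 0.0)]
            raise ValueError(f"zero-variance ROI column(s): {', '.join(dead)}")
        ti = (
            np.arange(values.shape[0], dtype=float)
            if self.time_index is None
            else np.asarray(self.time_index, dtype=float)
        )
        if ti.shape != (values.shape[0],):
            raise ValueError("time index length does not match sample count")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "roi_labels", labels)
        object.__setattr__(self, "time_index", ti)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    def column(self, label: str) -> np.ndarray:
        try:
            j = self.roi_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown ROI label {label!r}") from None
        return self.values[:, j]


def correlation_matrix(
    ts: RoiTimeSeries, source_tag: str = ""
) -> ConnectivityMatrix:
    """Pearson correlations between all ROI pairs.

    The diagonal is pinned to exactly 1 and off-diagonal values are clipped
    into [-1, 1] to absorb floating-point overshoot, so the result always
    satisfies the connectivity-matrix invariants.
    """
    c = np.corrcoef(ts.values, rowvar=False)
    c = np.clip(c, -1.0, 1.0)
    c = (c + c.T) / 2.0
    np.fill_diagonal(c, 1.0)
    return ConnectivityMatrix(values=c, labels=ts.roi_labels, source_tag=source_tag)


def synth_timeseries(
    n: int,
    T: int,
    coupling: np.ndarray | None = None,
    noise_scale: float = 1.0,
    seed: int | None = None,
    roi_labels: tuple[str, ...] = (),
) -> RoiTimeSeries:
    """Multivariate-Gaussian ROI series with a target correlation structure.

    ``coupling`` is a symmetric positive-semi-definite unit-diagonal matrix;
    the sample correlation matrix of the output converges to it as T grows
    (sampling error ~ 1/sqrt(T)).  ``noise_scale`` sets the signal amplitude
    and does not affect correlations.
    """
    if coupling is None:
        coupling = np.eye(n)
    coupling = np.asarray(coupling, dtype=float)
    if coupling.shape != (n, n):
        raise ValueError(f"coupling must be {n} x {n}")
    if np.max(np.abs(coupling - coupling.T)) > 1e-10:
        raise ValueError("coupling must be symmetric")
    if not np.allclose(np.diag(coupling), 1.0):
        raise ValueError("coupling must have a unit diagonal")
    eigmin = float(np.linalg.eigvalsh(coupling).min())
    if eigmin < -1e-10:
        raise ValueError(
            f"coupling is not positive semi-definite (min eigenvalue {eigmin:.3e})"
        )
    # eigen-factorisation tolerates the PSD-boundary case Cholesky rejects
    w, v = np.linalg.eigh(coupling)
    factor = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((T, n))
    x = noise_scale * (z @ factor.T)
    return RoiTimeSeries(values=x, roi_labels=roi_labels)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def write_timeseries(ts: RoiTimeSeries, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(ts.values, columns=list(ts.roi_labels))
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")
    return path


def read_timeseries(path: str | Path) -> RoiTimeSeries:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    if df.isnull().any().any():
        raise ValueError(f"time-series file {path} has missing cells")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"time-series file {path} contains non-numeric cells")
    return RoiTimeSeries(values=values, roi_labels=tuple(str(c) for c in df.columns))
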