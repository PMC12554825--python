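"""Recurrence plots, joint recurrence plots, and recurrence rates.

A recurrence plot (RP) of a scalar series x marks the time-point pairs whose
states lie within a threshold of each other:

    R_ij = Theta(eps - |x_i - x_j|),  Theta(0) = 1,

with no time-delay embedding, so the state is the scalar sample and the
Euclidean norm reduces to the absolute difference.  The joint RP of two
systems is the Hadamard product of their RPs, and the (joint) recurrence
rate is the density of ones including the diagonal:

    RR = (1/N^2) sum_ij R_ij,   JRR = (1/N^2) sum_ij JR_ij.

JRR is bounded by the smaller of the two individual RRs; JRR close to RR
signals generalised synchronisation of the two systems, vanishing JRR a
lack of shared dynamics.  Series are z-scored by default so that one eps
(default 0.3) is comparable across ROIs and sessions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .connectivity import RoiTimeSeries

__all__ = [
    "RecurrenceMatrix",
    "PairRecurrenceSession",
    "normalize_series",
    "recurrence_plot",
    "joint_recurrence_plot",
    "recurrence_rate",
    "joint_recurrence_rate",
    "pair_recurrence_report",
]

NORMALIZATIONS = ("zscore", "minmax", "none")

DEFAULT_EPSILON = 0.3


@dataclass(frozen=True)
class RecurrenceMatrix:
    """Binary N x N recurrence grid: symmetric with an all-ones diagonal."""

    values: np.ndarray
    epsilon: float
    norm_tag: str = "euclidean"
    normalization_tag: str = "none"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.uint8)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("recurrence matrix must be square")
        if not np.all((v == 0) | (v == 1)):
            raise ValueError("recurrence matrix entries must be 0 or 1")
        if not np.array_equal(v, v.T):
            raise ValueError("recurrence matrix must be symmetric")
        if not np.all(np.diag(v) == 1):
            raise ValueError("recurrence matrix diagonal must be all ones")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def normalize_series(x: np.ndarray, method: str = "zscore") -> np.ndarray:
    """Normalise a 1-D signal: zscore (mean 0, sd 1), minmax ([0, 1]) or none."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("signal must be 1-D with at least 2 samples")
    if method == "zscore":
        sd = x.std()
        if sd == 0.0:
            raise ValueError("cannot z-score a constant series")
        return (x - x.mean()) / sd
    if method == "minmax":
        lo, hi = x.min(), x.max()
        if hi == lo:
            return np.zeros_like(x)
        return (x - lo) / (hi - lo)
    if method == "none":
        return x.copy()
    raise ValueError(f"unknown normalization {method!r}; one of {NORMALIZATIONS}")


def recurrence_plot(
    x: np.ndarray, epsilon: float = DEFAULT_EPSILON, normalization: str = "none"
) -> RecurrenceMatrix:
    """RP of a scalar series: R_ij = 1 iff |x_i - x_j| <= epsilon.

    A distance exactly equal to epsilon counts as recurrent (Theta(0) = 1).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    x = normalize_series(np.asarray(x, dtype=float), normalization)
    dist = np.abs(x[:, None] - x[None, :])
    return RecurrenceMatrix(
        values=(dist <= epsilon).astype(np.uint8),
        epsilon=epsilon,
        norm_tag="euclidean",
        normalization_tag=normalization,
    )


def joint_recurrence_plot(
    ra: RecurrenceMatrix, rb: RecurrenceMatrix
) -> RecurrenceMatrix:
    """Hadamard product of two RPs: recurrent where both systems recur."""
    if ra.n != rb.n:
        raise ValueError(f"RP sizes differ: {ra.n} vs {rb.n}")
    return RecurrenceMatrix(
        values=ra.values * rb.values,
        epsilon=max(ra.epsilon, rb.epsilon),
        norm_tag=ra.norm_tag,
        normalization_tag=ra.normalization_tag,
    )


def recurrence_rate(r: RecurrenceMatrix) -> float:
    """Density of recurrence points, diagonal included: in (0, 1]."""
    return float(r.values.sum() / r.n**2)


def joint_recurrence_rate(jr: RecurrenceMatrix) -> float:
    """Recurrence rate of a joint RP; bounded by min of the individual RRs."""
    return recurrence_rate(jr)


@dataclass(frozen=True)
class PairRecurrenceSession:
    """Per-session recurrence summary for one ROI pair."""

    session_tag: str
    rr_a: float
    rr_b: float
    jrr: float
    rp_a: RecurrenceMatrix
    rp_b: RecurrenceMatrix
    jrp: RecurrenceMatrix
    epsilon: float
    normalization: str

    def to_dict(self) -> dict:
        return {
            "session": self.session_tag,
            "rr_a": self.rr_a,
            "rr_b": self.rr_b,
            "jrr": self.jrr,
            "epsilon": self.epsilon,
            "normalization": self.normalization,
        }


def pair_recurrence_report(
    sessions: Sequence[RoiTimeSeries],
    roi_a: str,
    roi_b: str,
    epsilon: float = DEFAULT_EPSILON,
    normalization: str = "zscore",
    session_tags: Sequence[str] | None = None,
) -> list[PairRecurrenceSession]:
    """RR/JRR of one ROI pair across imaging sessions.

    For each session, builds the RPs of both ROI signals (after the chosen
    normalisation), their joint RP, and the three rates.  A falling JRR
    across sessions indicates a loss of synchronisation between the two
    regions as the disease progresses.
    """
    if session_tags is None:
        session_tags = [f"session{i}" for i in range(len(sessions))]
    if len(session_tags) != len(sessions):
        raise ValueError("one tag per session is required")
    out = []
    for tag, ts in zip(session_tags, sessions):
        xa = ts.column(roi_a)
        xb = ts.column(roi_b)
        rp_a = recurrence_plot(xa, epsilon, normalization)
        rp_b = recurrence_plot(xb, epsilon, normalization)
        jrp = joint_recurrence_plot(rp_a, rp_b)
        out.append(
            PairRecurrenceSession(
                session_tag=tag,
                rr_a=recurrence_rate(rp_a),
                rr_b=recurrence_rate(rp_b),
                jrr=joint_recurrence_rate(jrp),
                rp_a=rp_a,
                rp_b=rp_b,
                jrp=jrp,
                epsilon=epsilon,
                normalization=normalization,
            )
        )
    return out
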