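"""End-to-end workflow: sessions -> K -> spectra -> measures -> ROI pairs.

Given two or more imaging sessions (connectivity matrices, or ROI time
series from which connectivity is computed), the pipeline computes the
K-operator between consecutive sessions with the chosen product, its
spectrum and network measures, selects the ROI pairs with the largest |K|,
fits linear and quadratic trends to their 2x2 connectivity submatrices,
and — when time series are available — runs the recurrence analysis for
each selected pair.  Every artefact is declared in a manifest and the run
is bit-reproducible for a fixed config.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import netmeasures, recurrence
from .connectivity import RoiTimeSeries, correlation_matrix, read_timeseries
from .dynamics import (
    DynamicsSeries,
    extract_pair_series,
    fit_linear,
    fit_quadratic,
    select_roi_pairs,
)
from .matrices import SquareMatrix, read_matrix, write_matrix
from .operators import (
    DEFAULT_ZERO_FLOOR,
    k_kernel,
    k_matrix_product,
    k_mixed,
    k_ratio,
)
from .spectral import eigen_spectrum

__all__ = ["PipelineConfig", "run_pipeline", "write_spectrum_csv"]

_K_FUNCS = {
    "matrix": k_matrix_product,
    "matrix_product": k_matrix_product,
    "mixed": k_mixed,
    "ratio": None,  # handled separately (no inversion)
    "kernel": k_kernel,
}


@dataclass
class PipelineConfig:
    """Parameters of one pipeline run.

    ``sessions`` are file paths ordered in time; each may be a connectivity
    matrix or an ROI time-series table (auto-detected by shape, overridable
    with ``input_kind``).  Defaults follow the reference analysis: ratio K,
    threshold 0.3, modularity shifts +1 for connectivity and +1000 for K,
    epsilon 0.3 with z-scored series, top 5 pairs.
    """

    sessions: list[str]
    out_dir: str
    k_method: str = "ratio"
    threshold: float = 0.3
    shift_connectivity: float = 1.0
    shift_k: float = 1000.0
    top_n: int = 5
    epsilon: float = 0.3
    normalization: str = "zscore"
    zero_floor: float = DEFAULT_ZERO_FLOOR
    seed: int = 0
    input_kind: str = "auto"  # auto | matrix | timeseries

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def validate(self) -> None:
        if len(self.sessions) < 2:
            raise ValueError("at least two sessions are required")
        if self.k_method not in _K_FUNCS:
            raise ValueError(
                f"unknown k_method {self.k_method!r}; one of {sorted(_K_FUNCS)}"
            )
        if self.input_kind not in ("auto", "matrix", "timeseries"):
            raise ValueError(f"unknown input_kind {self.input_kind!r}")
        for p in self.sessions:
            if not Path(p).exists():
                raise FileNotFoundError(f"session file not found: {p}")


def _load_session(
    path: str, kind: str
) -> tuple[SquareMatrix, RoiTimeSeries | None]:
    """Load one session file as (connectivity matrix, optional time series)."""
    if kind == "auto":
        df = pd.read_csv(path, sep="\t" if str(path).endswith(".tsv") else ",")
        kind = "matrix" if df.shape[0] == df.shape[1] else "timeseries"
    if kind == "matrix":
        return read_matrix(path), None
    ts = read_timeseries(path)
    return correlation_matrix(ts, source_tag=Path(path).stem), ts


def write_spectrum_csv(m: SquareMatrix, path: Path, order: str = "real_desc") -> None:
    spec = eigen_spectrum(m, order_rule=order, compute_vectors=False)
    pd.DataFrame(
        {
            "index": np.arange(len(spec)),
            "re": spec.eigenvalues.real,
            "im": spec.eigenvalues.imag,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def _compute_k(cfg: PipelineConfig, gk: SquareMatrix, g: SquareMatrix):
    if cfg.k_method == "ratio":
        return k_ratio(gk, g, zero_floor=cfg.zero_floor)
    return _K_FUNCS[cfg.k_method](gk, g)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full workflow; returns the run directory.

    Outputs: per-transition K matrix, eigenvalue CSV and measure report;
    per-session measure report; selected ROI pairs with their trajectory
    fits; recurrence reports when time series were supplied; a manifest
    recording every parameter and output file.  Reruns of the same config
    are byte-identical (the log carries no wall-clock timestamps).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    outputs: list[str] = []

    def log(stage: str, **params) -> None:
        kv = " ".join(f"{k}={v}" for k, v in params.items())
        log_lines.append(f"stage={stage} {kv}".rstrip())

    def declare(path: Path) -> Path:
        outputs.append(str(path.relative_to(out)))
        return path

    # --- load sessions -----------------------------------------------------
    sessions: list[SquareMatrix] = []
    series: list[RoiTimeSeries | None] = []
    for path in config.sessions:
        mat, ts = _load_session(path, config.input_kind)
        sessions.append(mat)
        series.append(ts)
        log("load", path=path, kind="timeseries" if ts is not None else "matrix",
            n=mat.n)
    first = sessions[0]
    for i, s in enumerate(sessions[1:], start=1):
        if s.values.shape != first.values.shape or s.labels != first.labels:
            raise ValueError(f"session {i} shape/labels mismatch with session 0")

    # --- per-session measures ---------------------------------------------
    for i, mat in enumerate(sessions):
        rep = netmeasures.measure_report(
            mat, tau=config.threshold, shift=config.shift_connectivity
        )
        p = declare(out / f"session{i}_measures.json")
        p.write_text(json.dumps(rep.to_dict(), indent=2, sort_keys=True))
        log("measures", target=f"session{i}", sparsity=f"{rep.sparsity:.6g}",
            modularity=f"{rep.modularity:.6g}")

    # --- K per consecutive pair -------------------------------------------
    k_list = []
    for t in range(len(sessions) - 1):
        k = _compute_k(config, sessions[t + 1], sessions[t])
        k_list.append(k)
        write_matrix(k, declare(out / f"K_{t}{t + 1}.csv"))
        write_spectrum_csv(k, declare(out / f"K_{t}{t + 1}_eigs.csv"))
        rep = netmeasures.measure_report(
            k, tau=config.threshold, shift=config.shift_k
        )
        p = declare(out / f"K_{t}{t + 1}_measures.json")
        p.write_text(json.dumps(rep.to_dict(), indent=2, sort_keys=True))
        log("koperator", transition=f"{t}->{t + 1}", method=config.k_method,
            sparsity=f"{rep.sparsity:.6g}")

    # --- ROI-pair selection and trajectory fits ----------------------------
    pairs = select_roi_pairs(k_list[0], top_n=min(config.top_n,
                                                  first.n * (first.n - 1) // 2))
    conn_series = DynamicsSeries(matrices=tuple(sessions))
    pair_records = []
    for lab_a, lab_b, k_val in pairs:
        sub = extract_pair_series(conn_series, lab_a, lab_b)
        lin = fit_linear(sub)
        record = {
            "roi_a": lab_a,
            "roi_b": lab_b,
            "k_value": k_val,
            "linear": {
                "a": lin.element(0, 1)[0],
                "b": lin.element(0, 1)[1],
                "residual_sse": float(lin.residual_sse[0, 1]),
            },
        }
        if len(sessions) >= 3:
            quad = fit_quadratic(sub)
            record["quadratic"] = {
                "a": quad.element(0, 1)[0],
                "b": quad.element(0, 1)[1],
                "c": quad.element(0, 1)[2],
                "residual_sse": float(quad.residual_sse[0, 1]),
            }
        pair_records.append(record)
        log("pair_fit", roi_a=lab_a, roi_b=lab_b, k=f"{k_val:.6g}")
    p = declare(out / "selected_pairs.json")
    p.write_text(json.dumps(pair_records, indent=2, sort_keys=True))

    # --- recurrence analysis (time-series inputs only) ----------------------
    if all(ts is not None for ts in series):
        for lab_a, lab_b, _ in pairs:
            report = recurrence.pair_recurrence_report(
                [ts for ts in series if ts is not None],
                lab_a,
                lab_b,
                epsilon=config.epsilon,
                normalization=config.normalization,
            )
            safe = f"{lab_a}_{lab_b}".replace("/", "-")
            p = declare(out / f"recurrence_{safe}.json")
            p.write_text(
                json.dumps([s.to_dict() for s in report], indent=2, sort_keys=True)
            )
            log("recurrence", roi_a=lab_a, roi_b=lab_b,
                jrr=" ".join(f"{s.jrr:.6g}" for s in report))

    # --- manifest & log -----------------------------------------------------
    log_path = out / "run.log"
    log_path.write_text("\n".join(log_lines) + "\n")
    outputs.append("run.log")
    manifest = {
        "config": asdict(config),
        "outputs": sorted(outputs),
        "n_sessions": len(sessions),
        "n_rois": first.n,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return out
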