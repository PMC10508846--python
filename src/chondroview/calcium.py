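"""Ratiometric Ca²⁺ trace analysis.

Fura-2 traces (340/380 nm excitation ratio, optionally calibrated to nM)
are scored per cell: the resting level [Ca²⁺]₀ is the mean over the
pre-treatment window, a cell is *responsive* if its post-treatment peak
rises at least ``k`` baseline standard deviations above the resting level
(``k = 3`` by default), and the agonist-evoked Δ[Ca²⁺] is the mean of
(peak − baseline) over responsive cells only.

The criterion boundary is inclusive: peak − baseline == k·SD counts as
responsive. The baseline window is every sample strictly before the
treatment time; the response window runs from the treatment time to the
end of the recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class TraceSet:
    """Per-cell calcium time series on a shared time grid.

    ``values`` has shape ``(n_samples, n_cells)``; ``time`` is strictly
    increasing, in seconds, and ``treatment_time`` (agonist addition)
    must fall inside ``[time[0], time[-1])``.
    """

    time: np.ndarray
    values: np.ndarray
    treatment_time: float
    cell_ids: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.time.shape[0]:
            raise ValueError(
                f"{self.values.shape[0]} rows of values for {self.time.shape[0]} time points"
            )
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not (self.time[0] <= self.treatment_time < self.time[-1]):
            raise ValueError(
                f"treatment_time {self.treatment_time} outside [{self.time[0]}, {self.time[-1]})"
            )
        if not self.cell_ids:
            self.cell_ids = tuple(f"cell_{i + 1:03d}" for i in range(self.n_cells))
        if len(self.cell_ids) != self.n_cells:
            raise ValueError("one cell id per column required")

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def trace(self, i: int) -> np.ndarray:
        return self.values[:, i]


@dataclass
class CellResponse:
    """Per-cell scoring: baseline statistics, peak, and the responsive flag."""

    cell_id: str
    baseline_mean: float
    baseline_sd: float
    peak: float
    peak_time: float
    responsive: bool
    delta: float | None  # peak - baseline, responsive cells only


@dataclass
class ResponsivenessResult:
    """Set-level summary of a :class:`TraceSet`.

    ``resting_mean`` averages baselines over *all* cells; ``delta_mean``
    (Δ[Ca²⁺]) averages peak − baseline over responsive cells only and is
    ``None`` when no cell responded.
    """

    cells: list[CellResponse]
    k: float
    resting_mean: float
    responder_fraction: float
    delta_mean: float | None

    @property
    def n_responsive(self) -> int:
        return sum(c.responsive for c in self.cells)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": [c.cell_id for c in self.cells],
                "baseline_mean": [c.baseline_mean for c in self.cells],
                "baseline_sd": [c.baseline_sd for c in self.cells],
                "peak": [c.peak for c in self.cells],
                "peak_time": [c.peak_time for c in self.cells],
                "responsive": [c.responsive for c in self.cells],
                "delta": [c.delta if c.delta is not None else np.nan for c in self.cells],
            }
        )

    def summary_dict(self) -> dict:
        return {
            "n_cells": len(self.cells),
            "n_responsive": self.n_responsive,
            "responder_fraction": self.responder_fraction,
            "resting_mean": self.resting_mean,
            "delta_mean": self.delta_mean,
            "k": self.k,
        }


def compute_ratio(
    numerator: np.ndarray, denominator: np.ndarray, floor: float = 1e-6
) -> tuple[np.ndarray, int]:
    """Elementwise 340/380 excitation ratio with a floor guarding division.

    Returns ``(ratio, n_floored)`` where ``n_floored`` counts samples at
    which the denominator fell below ``floor`` (a QC signal: the 380-nm
    channel should never reach zero in a well-loaded cell).
    """
    numerator = np.asarray(numerator, dtype=float)
    denominator = np.asarray(denominator, dtype=float)
    if numerator.shape != denominator.shape:
        raise ValueError("numerator and denominator must share the time grid")
    if not floor > 0:
        raise ValueError("floor must be > 0")
    n_floored = int(np.count_nonzero(denominator < floor))
    return numerator / np.maximum(denominator, floor), n_floored


def baseline_stats(
    trace: np.ndarray, time: np.ndarray, treatment_time: float
) -> tuple[float, float]:
    """Mean and sample SD over all samples strictly before the treatment.

    Requires at least three pre-treatment samples — the sample SD is
    meaningless below that.
    """
    trace = np.asarray(trace, dtype=float)
    time = np.asarray(time, dtype=float)
    pre = trace[time < treatment_time]
    if pre.size < 3:
        raise ValueError(
            f"need >= 3 samples before treatment_time {treatment_time}, got {pre.size}"
        )
    return float(pre.mean()), float(pre.std(ddof=1))


def classify_responsive(
    trace: np.ndarray,
    time: np.ndarray,
    treatment_time: float,
    baseline_mean: float,
    baseline_sd: float,
    k: float = 3.0,
) -> tuple[bool, float, float]:
    """Apply the k·SD responder criterion to one trace.

    The peak is the maximum over the response window (treatment time to
    trace end, inclusive on both sides); the cell is responsive iff
    ``peak − baseline_mean >= k × baseline_sd``.

    Returns ``(responsive, peak, peak_time)``.
    """
    trace = np.asarray(trace, dtype=float)
    time = np.asarray(time, dtype=float)
    window = time >= treatment_time
    if not window.any():
        raise ValueError("empty response window")
    seg = trace[window]
    i = int(np.argmax(seg))
    peak = float(seg[i])
    peak_time = float(time[window][i])
    # inclusive boundary, robust to float rounding of peak = mean + k*sd
    diff = peak - baseline_mean
    threshold = k * baseline_sd
    responsive = diff >= threshold or bool(
        np.isclose(diff, threshold, rtol=1e-9, atol=1e-12)
    )
    return bool(responsive), peak, peak_time


def analyze_traceset(traces: TraceSet, k: float = 3.0) -> ResponsivenessResult:
    """Score every cell and summarize the set (see :func:`summarize_set`)."""
    cells = []
    for i in range(traces.n_cells):
        tr = traces.trace(i)
        mean, sd = baseline_stats(tr, traces.time, traces.treatment_time)
        responsive, peak, peak_time = classify_responsive(
            tr, traces.time, traces.treatment_time, mean, sd, k=k
        )
        cells.append(
            CellResponse(
                cell_id=traces.cell_ids[i],
                baseline_mean=mean,
                baseline_sd=sd,
                peak=peak,
                peak_time=peak_time,
                responsive=responsive,
                delta=(peak - mean) if responsive else None,
            )
        )
    return summarize_set(cells, k=k)


def summarize_set(cells: list[CellResponse], k: float = 3.0) -> ResponsivenessResult:
    """Set-level statistics from per-cell scores.

    Resting [Ca²⁺]₀ averages baselines over all cells; Δ[Ca²⁺] averages
    peak − baseline over responsive cells only and is reported as missing
    (``None``) — never as 0 — when no cell responded.
    """
    if not cells:
        raise ValueError("no cells to summarize")
    resting = float(np.mean([c.baseline_mean for c in cells]))
    deltas = [c.delta for c in cells if c.responsive]
    delta_mean = float(np.mean(deltas)) if deltas else None
    return ResponsivenessResult(
        cells=cells,
        k=k,
        resting_mean=resting,
        responder_fraction=len(deltas) / len(cells),
        delta_mean=delta_mean,
    )


def read_traces_csv(path: str | Path, treatment_time: float) -> TraceSet:
    """Read a trace CSV: first column ``time_s``, one column per cell."""
    df = pd.read_csv(path)
    if df.columns[0] != "time_s":
        raise ValueError(f"first column must be time_s, got {df.columns[0]!r}")
    return TraceSet(
        time=df["time_s"].to_numpy(),
        values=df.iloc[:, 1:].to_numpy(),
        treatment_time=treatment_time,
        cell_ids=tuple(df.columns[1:]),
    )


def write_traces_csv(traces: TraceSet, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(traces.values, columns=list(traces.cell_ids))
    df.insert(0, "time_s", traces.time)
    df.to_csv(path, index=False)
    return path
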