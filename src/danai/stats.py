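"""Time series, summary statistics and mode-mode correlations of motif counts.

The correlation is Pearson's coefficient computed from deviations about the
per-series mean; a series with zero variance has no defined correlation with
anything and is reported as a missing value (None / empty CSV cell), never
silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import StructuralError
from .motif_count import ModeCounts

__all__ = [
    "CountTimeSeries",
    "SummaryRow",
    "CorrelationMatrix",
    "build_series",
    "summarize",
    "correlate",
    "correlation_matrix",
    "write_counts_csv",
    "read_counts_csv",
    "write_summary_csv",
    "write_correlation_csv",
]


@dataclass
class CountTimeSeries:
    mode: str
    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.times.shape != self.counts.shape:
            raise StructuralError("times and counts must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise StructuralError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class SummaryRow:
    mode: str
    mean_mu: float
    deviation: float


@dataclass
class CorrelationMatrix:
    modes: list[str]
    values: np.ndarray  # NaN marks undefined entries

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.modes)
        if self.values.shape != (n, n):
            raise StructuralError("correlation matrix shape mismatch")

    def get(self, x: str, y: str) -> float | None:
        i, j = self.modes.index(x), self.modes.index(y)
        v = self.values[i, j]
        return None if math.isnan(v) else float(v)


def build_series(per_frame: Sequence[ModeCounts]) -> list[CountTimeSeries]:
    """One series per mode, in the mode order of the first frame."""
    per_frame = list(per_frame)
    if not per_frame:
        raise StructuralError("no frames to assemble")
    keys = list(per_frame[0].counts.keys())
    keyset = set(keys)
    for mc in per_frame:
        if set(mc.counts.keys()) != keyset:
            raise StructuralError("inconsistent mode keys across frames")
    times = np.array([mc.time for mc in per_frame], dtype=float)
    return [
        CountTimeSeries(
            mode=k,
            times=times,
            counts=np.array([mc.counts[k] for mc in per_frame]),
        )
        for k in keys
    ]


def summarize(s: CountTimeSeries, ddof: int = 0) -> SummaryRow:
    """Arithmetic mean and standard deviation (population by default;
    ``ddof=1`` for the sample convention)."""
    if len(s) < 1:
        raise StructuralError("cannot summarize an empty series")
    x = np.asarray(s.counts, dtype=float)
    return SummaryRow(
        mode=s.mode,
        mean_mu=float(np.mean(x)),
        deviation=float(np.std(x, ddof=ddof)) if len(x) > ddof else 0.0,
    )


def correlate(x: CountTimeSeries, y: CountTimeSeries) -> float | None:
    """Pearson correlation of two equally sampled series; None if either is
    constant (undefined, not zero)."""
    if len(x) != len(y):
        raise StructuralError("series length mismatch")
    if len(x) < 2:
        raise StructuralError("correlation requires at least 2 samples")
    dx = np.asarray(x.counts, dtype=float) - np.mean(x.counts)
    dy = np.asarray(y.counts, dtype=float) - np.mean(y.counts)
    vx = float(np.mean(dx * dx))
    vy = float(np.mean(dy * dy))
    if vx == 0.0 or vy == 0.0:
        return None
    r = float(np.mean(dx * dy) / math.sqrt(vx * vy))
    # clamp IEEE round-off just past the bounds
    return max(-1.0, min(1.0, r))


def correlation_matrix(series: Sequence[CountTimeSeries]) -> CorrelationMatrix:
    """Symmetric Pearson matrix in the given series order; exact 1.0 on the
    diagonal for non-constant series, NaN where undefined."""
    series = list(series)
    if not series:
        raise StructuralError("no series given")
    lengths = {len(s) for s in series}
    if len(lengths) > 1:
        raise StructuralError("series length mismatch")
    n = len(series)
    vals = np.full((n, n), np.nan)
    for i in range(n):
        xi = np.asarray(series[i].counts, dtype=float)
        const_i = np.all(xi == xi[0])
        if not const_i:
            vals[i, i] = 1.0
        for j in range(i + 1, n):
            r = correlate(series[i], series[j])
            if r is not None:
                vals[i, j] = vals[j, i] = r
    return CorrelationMatrix(modes=[s.mode for s in series], values=vals)


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------


def write_counts_csv(per_frame: Sequence[ModeCounts], path: str | Path) -> None:
    per_frame = list(per_frame)
    if not per_frame:
        raise StructuralError("no frames to write")
    keys = list(per_frame[0].counts.keys())
    rows = [
        {"step": mc.frame_step, "time_ps": mc.time, **{k: mc.counts[k] for k in keys}}
        for mc in per_frame
    ]
    pd.DataFrame(rows, columns=["step", "time_ps", *keys]).to_csv(path, index=False)


def read_counts_csv(path: str | Path) -> list[ModeCounts]:
    df = pd.read_csv(path)
    if "step" not in df.columns or "time_ps" not in df.columns:
        raise StructuralError(f"{path}: missing step/time_ps columns")
    modes = [c for c in df.columns if c not in ("step", "time_ps")]
    if not modes:
        raise StructuralError(f"{path}: no mode columns")
    return [
        ModeCounts(
            frame_step=int(row["step"]),
            time=float(row["time_ps"]),
            counts={m: int(row[m]) for m in modes},
        )
        for _, row in df.iterrows()
    ]


def write_summary_csv(rows: Sequence[SummaryRow], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "mode": [r.mode for r in rows],
            "mean": [round(r.mean_mu, 4) for r in rows],
            "deviation": [round(r.deviation, 6) for r in rows],
        }
    )
    df.to_csv(path, index=False)


def write_correlation_csv(matrix: CorrelationMatrix, path: str | Path) -> None:
    n = len(matrix.modes)
    cells = [
        ["" if math.isnan(matrix.values[i, j]) else f"{matrix.values[i, j]:.3f}" for j in range(n)]
        for i in range(n)
    ]
    df = pd.DataFrame(cells, index=matrix.modes, columns=matrix.modes)
    df.to_csv(path, index_label="mode")
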