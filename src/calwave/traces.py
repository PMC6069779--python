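"""Raw trace conditioning: background, smoothing, bleaching, peak calling.

The processing chain mirrors the standard single-wavelength indicator
workflow: subtract a scalar background, smooth with a 5-point moving
average, estimate quiescent baselines at the start and end of the
recording, divide out an interpolated bleaching curve so the quiescent
level sits at F/F0 = 1, and call transient peaks at an amplitude threshold
of 1.1 (a 10 % rise over baseline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .detection import TraceSet

#: columns of a peak table
PEAK_COLUMNS = ["cell_id", "peak_frame", "peak_time_s", "amplitude"]


@dataclass
class ProcessedTrace:
    """A normalized, bleach-corrected F/F0 trace for one cell."""

    values: np.ndarray
    baseline_start: float
    baseline_end: float
    background_value: float = 0.0
    smoothing_span: int = 5

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("processed trace contains non-finite values")


def subtract_background(
    traces: TraceSet,
    background: float | None = None,
    avg_image: np.ndarray | None = None,
    floor: float = 1e-3,
) -> tuple[TraceSet, float]:
    """Subtract one scalar background per movie from every trace.

    ``background=None`` selects auto mode: the 5th percentile of the
    temporally averaged image, which in a monolayer recording samples the
    cell-free (or dimmest) pixels.  Values that would go non-positive are
    clipped at ``floor`` with a warning.
    """
    if background is None:
        if avg_image is None:
            raise ValueError("auto background needs the averaged image")
        background = float(np.percentile(np.asarray(avg_image, dtype=float), 5))
    if background < 0:
        raise ValueError("background must be non-negative")
    out = traces.traces - background
    if background > 0 and (out <= 0).any():
        warnings.warn(
            "background exceeds some trace values; clipping at the floor",
            stacklevel=2,
        )
        out = np.maximum(out, floor)
    return (
        TraceSet(out, frame_rate=traces.frame_rate, cells=traces.cells,
                 source=traces.source),
        background,
    )


def smooth(trace: np.ndarray, span: int = 5) -> np.ndarray:
    """Centered moving average along the last axis.

    At the edges the window shrinks to the available samples, e.g. with
    ``span=5`` the first point averages indices 0..2.  ``span`` must be odd;
    ``span=1`` is the identity.
    """
    if span < 1 or span % 2 == 0:
        raise ValueError("span must be an odd integer >= 1")
    trace = np.asarray(trace, dtype=float)
    n = trace.shape[-1]
    h = span // 2
    csum = np.concatenate(
        [np.zeros(trace.shape[:-1] + (1,)), np.cumsum(trace, axis=-1)], axis=-1
    )
    idx = np.arange(n)
    lo = np.maximum(0, idx - h)
    hi = np.minimum(n, idx + h + 1)
    return (csum[..., hi] - csum[..., lo]) / (hi - lo)


def estimate_baselines(
    trace: np.ndarray, window_frames: int = 30
) -> tuple[float, float]:
    """Robust quiescent baselines of the first and last window.

    Each window's baseline is the median after one round of transient
    exclusion: frames more than 5 % above the window median are dropped and
    the median recomputed.  This keeps a transient that happens to start or
    end inside the window from inflating the estimate.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.shape[-1]
    if window_frames < 1:
        raise ValueError("window_frames must be >= 1")
    if 2 * window_frames > n:
        raise ValueError("baseline windows longer than half the trace")

    def robust(window: np.ndarray) -> float:
        med = np.median(window)
        keep = window[window <= med * 1.05] if med > 0 else window
        if keep.size == 0:
            keep = window
        return float(np.median(keep))

    return robust(trace[:window_frames]), robust(trace[-window_frames:])


def correct_bleaching_and_normalize(
    trace: np.ndarray,
    baselines: tuple[float, float],
    anchor_frames: tuple[float, float] | None = None,
    mode: str = "exponential",
    background_value: float = 0.0,
    smoothing_span: int = 5,
) -> ProcessedTrace:
    """Divide a trace by an interpolated bleaching baseline.

    The baseline curve ``b(t)`` passes through ``baseline_start`` at the
    first anchor frame and ``baseline_end`` at the last (defaults: first and
    last frame of the trace).  ``mode`` selects an exponential (default,
    matching first-order photobleaching) or linear interpolant.  The result
    is a dimensionless F/F0 trace whose quiescent level is ~1 at both ends.
    """
    b0, b1 = baselines
    if b0 <= 0 or b1 <= 0:
        raise ValueError("baselines must be positive")
    if mode not in ("exponential", "linear"):
        raise ValueError("mode must be 'exponential' or 'linear'")
    trace = np.asarray(trace, dtype=float)
    n = trace.shape[-1]
    t0, t1 = anchor_frames if anchor_frames is not None else (0.0, float(n - 1))
    if t1 <= t0:
        raise ValueError("anchor frames must be increasing")
    t = np.arange(n, dtype=float)
    frac = (t - t0) / (t1 - t0)
    if mode == "exponential":
        b = b0 * (b1 / b0) ** frac
    else:
        b = b0 + (b1 - b0) * frac
    return ProcessedTrace(
        values=trace / b,
        baseline_start=b0,
        baseline_end=b1,
        background_value=background_value,
        smoothing_span=smoothing_span,
    )


def detect_peaks(
    processed: ProcessedTrace | np.ndarray,
    frame_rate: float,
    threshold: float = 1.1,
    min_prominence: float = 0.05,
    min_separation_s: float = 5.0,
    cell_id: int = 0,
) -> pd.DataFrame:
    """Call transient peaks on a normalized F/F0 trace.

    Local maxima with amplitude >= ``threshold`` (inclusive) and prominence
    >= ``min_prominence``, separated by at least ``min_separation_s``.  The
    default threshold 1.1 marks a 10 % rise over the quiescent level; values
    <= 1 are rejected as meaningless against a baseline of 1.
    """
    if threshold <= 1.0:
        raise ValueError("threshold must exceed the baseline level of 1")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    values = processed.values if isinstance(processed, ProcessedTrace) else (
        np.asarray(processed, dtype=float)
    )
    distance = max(1, int(round(min_separation_s * frame_rate)))
    idx, _ = find_peaks(
        values, height=threshold, prominence=min_prominence, distance=distance
    )
    return pd.DataFrame(
        {
            "cell_id": cell_id,
            "peak_frame": idx.astype(int),
            "peak_time_s": idx / frame_rate,
            "amplitude": values[idx],
        },
        columns=PEAK_COLUMNS,
    )


def empty_peak_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": pd.Series(dtype=int),
            "peak_frame": pd.Series(dtype=int),
            "peak_time_s": pd.Series(dtype=float),
            "amplitude": pd.Series(dtype=float),
        }
    )


def process_traceset(
    traces: TraceSet,
    background: float = 0.0,
    smoothing_span: int = 5,
    baseline_window: int = 30,
    bleach_mode: str = "exponential",
    threshold: float = 1.1,
    min_prominence: float = 0.05,
    min_separation_s: float = 5.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Run the full conditioning chain on every trace of a TraceSet.

    Returns the processed ``(n_cells, n_frames)`` F/F0 matrix and the
    concatenated peak table.  Baselines are anchored at the centers of the
    first and last baseline window so that a purely exponential bleach
    cancels exactly.
    """
    raw = np.maximum(traces.traces - background, 1e-3)
    n = traces.n_frames
    anchors = ((baseline_window - 1) / 2.0, n - 1 - (baseline_window - 1) / 2.0)
    processed = np.empty_like(raw)
    tables = []
    for i in range(traces.n_cells):
        sm = smooth(raw[i], smoothing_span)
        bl = estimate_baselines(sm, baseline_window)
        pt = correct_bleaching_and_normalize(
            sm, bl, anchor_frames=anchors, mode=bleach_mode,
            background_value=background, smoothing_span=smoothing_span,
        )
        processed[i] = pt.values
        tables.append(
            detect_peaks(
                pt, traces.frame_rate, threshold=threshold,
                min_prominence=min_prominence,
                min_separation_s=min_separation_s, cell_id=i,
            )
        )
    peaks = (
        pd.concat(tables, ignore_index=True) if tables else empty_peak_table()
    )
    return processed, peaks
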