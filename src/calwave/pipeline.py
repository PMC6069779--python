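"""End-to-end movie analysis: detect -> extract -> process -> peaks.

Thin orchestration over the per-stage modules, used by the command-line
interface and by recovery studies on synthetic recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import CellMap, TraceSet, average_image, detect_cells, extract_traces
from .traces import process_traceset


@dataclass
class PipelineResult:
    cells: CellMap
    traces: TraceSet
    processed: np.ndarray  # (n_cells, n_frames) F/F0
    peaks: pd.DataFrame
    background: float
    frame_rate: float

    @property
    def responsive_cell_ids(self) -> set[int]:
        return set(self.peaks["cell_id"].unique()) if len(self.peaks) else set()


def analyze_movie(
    movie: np.ndarray,
    radius_px: float,
    pixel_size_um: float,
    frame_rate: float,
    cells: CellMap | None = None,
    background: float | str = "auto",
    smoothing_span: int = 5,
    baseline_window: int = 30,
    bleach_mode: str = "exponential",
    threshold: float = 1.1,
    min_prominence: float = 0.05,
    min_separation_s: float = 5.0,
) -> PipelineResult:
    """Run the full single-movie pipeline.

    ``cells=None`` detects centers on the temporal average; pass a CellMap
    (e.g. manually drawn ROIs) to skip detection.  ``background="auto"``
    estimates the movie background as the 5th percentile of the averaged
    image.
    """
    avg = average_image(movie)
    if cells is None:
        cells = detect_cells(avg, radius_px, pixel_size_um=pixel_size_um)
    if cells.n_cells == 0:
        raise ValueError("no cells detected in the movie")
    traces = extract_traces(movie, cells, frame_rate=frame_rate)
    bg = (
        float(np.percentile(avg, 5)) if background == "auto" else float(background)
    )
    processed, peaks = process_traceset(
        traces,
        background=bg,
        smoothing_span=smoothing_span,
        baseline_window=baseline_window,
        bleach_mode=bleach_mode,
        threshold=threshold,
        min_prominence=min_prominence,
        min_separation_s=min_separation_s,
    )
    return PipelineResult(
        cells=cells, traces=traces, processed=processed, peaks=peaks,
        background=bg, frame_rate=frame_rate,
    )
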