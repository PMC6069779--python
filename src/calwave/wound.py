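"""Scratch-wound closure kinetics from time-lapse wound-mask series.

Input is an ordered series of binary wound masks with timestamps in hours
(segmentation of the raw phase-contrast frames is upstream of this module;
a simple threshold + morphology helper for synthetic images is provided).
Wound size is the pixel count of the mask; healing time is the timestamp of
the first fully closed frame; healing speed is the initial wound size in
pixels divided by the healing time in hours.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import filters, morphology

COATING_STATES = ("intact", "damaged", "unknown")


@dataclass
class WoundSeries:
    """Ordered (timestamp_h, wound_mask) series for one sample."""

    timestamps_h: np.ndarray
    masks: np.ndarray  # (n_frames, h, w), binary
    sample_id: str = ""
    coating_status: str = "unknown"

    def __post_init__(self) -> None:
        self.timestamps_h = np.asarray(self.timestamps_h, dtype=float)
        self.masks = np.asarray(self.masks)
        if self.masks.ndim != 3 or len(self.masks) != len(self.timestamps_h):
            raise ValueError("need one mask per timestamp, all same shape")
        if np.any(np.diff(self.timestamps_h) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.coating_status not in COATING_STATES:
            raise ValueError(f"coating_status must be one of {COATING_STATES}")

    @property
    def n_frames(self) -> int:
        return len(self.timestamps_h)


@dataclass
class HealingMetrics:
    initial_area_px: int
    healed: bool
    healing_time_h: float  # NaN when not healed
    healing_speed_px_per_h: float  # NaN when not healed
    sample_id: str = ""
    coating_status: str = "unknown"


def wound_area_series(series: WoundSeries) -> np.ndarray:
    """Wound pixel count per frame; masks must be binary."""
    masks = series.masks
    uniq = np.unique(masks)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("masks must be binary (0/1 or bool)")
    return masks.reshape(series.n_frames, -1).sum(axis=1).astype(int)


def healing_metrics(
    series: WoundSeries, closure_epsilon: float = 0.0
) -> HealingMetrics:
    """Healing time and speed of one wound series.

    Healing time is the timestamp of the first frame whose area is
    <= ``closure_epsilon`` pixels (no interpolation between frames, so the
    resolution equals the imaging interval).  Speed is defined only for
    healed samples, as initial area / healing time.
    """
    areas = wound_area_series(series)
    initial = int(areas[0])
    if initial <= 0:
        raise ValueError("no wound at t0 (initial area is 0)")
    closed = np.flatnonzero(areas <= closure_epsilon)
    if closed.size == 0:
        return HealingMetrics(
            initial, False, float("nan"), float("nan"),
            sample_id=series.sample_id, coating_status=series.coating_status,
        )
    t = float(series.timestamps_h[closed[0]])
    return HealingMetrics(
        initial, True, t, initial / t,
        sample_id=series.sample_id, coating_status=series.coating_status,
    )


def metrics_frame(
    entries: list[tuple[HealingMetrics, str]]
) -> pd.DataFrame:
    """Tabulate (metrics, condition) pairs for :func:`cohort_summary`."""
    rows = []
    for m, condition in entries:
        rows.append(
            {
                "sample_id": m.sample_id,
                "condition": condition,
                "coating_status": m.coating_status,
                "initial_area_px": m.initial_area_px,
                "healed": m.healed,
                "healing_time_h": m.healing_time_h,
                "healing_speed_px_per_h": m.healing_speed_px_per_h,
            }
        )
    return pd.DataFrame(rows)


def cohort_summary(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-condition percent healed and mean +/- SEM healing time and speed.

    Percent healed is computed over all samples of the condition (damaged
    and intact coating alike); time and speed summaries use only healed
    samples with intact coating, where the substrate did not confound the
    assay.  Percent healed is additionally reported rounded to the nearest
    integer, as is conventional; full precision stays in the table.
    """
    if frame.empty:
        raise ValueError("empty metrics table")
    rows = []
    for condition, grp in frame.groupby("condition", sort=True):
        n = len(grp)
        if n == 0:
            warnings.warn(f"condition {condition} has no samples; omitted",
                          stacklevel=2)
            continue
        n_healed = int(grp["healed"].sum())
        ok = grp[grp["healed"] & (grp["coating_status"] == "intact")]
        def msem(col: str) -> tuple[float, float]:
            v = ok[col].to_numpy(dtype=float)
            if v.size == 0:
                return float("nan"), float("nan")
            sem = (
                v.std(ddof=1) / math.sqrt(v.size) if v.size > 1 else float("nan")
            )
            return float(v.mean()), sem
        tm, tsem = msem("healing_time_h")
        sm, ssem = msem("healing_speed_px_per_h")
        pct = 100.0 * n_healed / n
        rows.append(
            {
                "condition": condition,
                "n_total": n,
                "n_healed": n_healed,
                "percent_healed": pct,
                "percent_healed_rounded": int(round(pct)),
                "n_intact_healed": len(ok),
                "mean_healing_time_h": tm,
                "sem_healing_time_h": tsem,
                "mean_healing_speed_px_per_h": sm,
                "sem_healing_speed_px_per_h": ssem,
            }
        )
    return pd.DataFrame(rows)


def segment_wound_synthetic(image: np.ndarray) -> np.ndarray:
    """Threshold + morphology wound segmentation for SYNTHETIC images only.

    Intended for the generator's rendered frames, where the denuded lane is
    darker than the monolayer: Otsu threshold, closing, and largest dark
    component.  Real phase-contrast wound segmentation is out of scope.
    """
    img = np.asarray(image, dtype=float)
    dark = img < filters.threshold_otsu(img)
    dark = morphology.closing(dark, morphology.disk(3))
    labeled = morphology.label(dark)
    if labeled.max() == 0:
        return np.zeros_like(dark, dtype=bool)
    sizes = np.bincount(labeled.ravel())
    sizes[0] = 0
    return labeled == int(np.argmax(sizes))


def load_mask_series(
    mask_dir: str | Path,
    times_csv: str | Path,
    sample_id: str = "",
    coating_status: str = "unknown",
) -> WoundSeries:
    """Read a mask series from a directory plus a (filename, hours) CSV."""
    import tifffile
    from imageio.v3 import imread

    table = pd.read_csv(times_csv)
    if not {"filename", "hours"} <= set(table.columns):
        raise ValueError("times CSV needs 'filename' and 'hours' columns")
    table = table.sort_values("hours")
    masks = []
    for name in table["filename"]:
        path = Path(mask_dir) / str(name)
        arr = (
            tifffile.imread(path)
            if path.suffix.lower() in (".tif", ".tiff")
            else imread(path)
        )
        masks.append((np.asarray(arr) > 0).astype(np.uint8))
    return WoundSeries(
        table["hours"].to_numpy(dtype=float), np.stack(masks),
        sample_id=sample_id, coating_status=coating_status,
    )
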