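"""Cell-center detection and fixed-radius ROI trace extraction.

Cells in a confluent epithelial monolayer imaged with a cytosolic calcium
indicator are approximated as fixed-sized circles.  Centers are found on the
temporally averaged fluorescence image (averaging suppresses transient
activity and leaves the anatomical baseline pattern), and one mean-intensity
trace per cell is then read out from a circular region of interest of a
single shared radius.

Coordinate convention used throughout the package: 0-based pixel indices,
``(x, y) = (column, row)``.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree


@dataclass
class CellMap:
    """Detected (or imported) cell centers with one shared circular radius.

    Parameters
    ----------
    centers
        ``(n, 2)`` float array of ``(x, y)`` pixel coordinates.
    radius_px
        Shared ROI radius in pixels, > 0.
    pixel_size_um
        Physical pixel size in micrometres per pixel.
    field_size
        ``(height, width)`` of the image the centers live in.
    """

    centers: np.ndarray
    radius_px: float
    pixel_size_um: float
    field_size: tuple[int, int]

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.size == 0:
            self.centers = np.zeros((0, 2))
        if self.centers.shape[1] != 2:
            raise ValueError("centers must be an (n, 2) array of (x, y) pairs")
        if self.radius_px <= 0:
            raise ValueError("radius_px must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        h, w = self.field_size
        xs, ys = self.centers[:, 0], self.centers[:, 1]
        bad = np.flatnonzero((xs < 0) | (xs > w - 1) | (ys < 0) | (ys > h - 1))
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"ROI {i} at ({xs[i]:g}, {ys[i]:g}) lies outside the "
                f"{h}x{w} field"
            )
        if len(self.centers) > 1:
            d, _ = cKDTree(self.centers).query(self.centers, k=2)
            if d[:, 1].min() <= self.radius_px:
                warnings.warn(
                    "some cell centers are closer than one ROI radius; "
                    "overlapping ROIs will share pixels",
                    stacklevel=2,
                )

    @property
    def n_cells(self) -> int:
        return len(self.centers)

    @property
    def radius_um(self) -> float:
        return self.radius_px * self.pixel_size_um

    @property
    def centers_um(self) -> np.ndarray:
        """Centers in micrometres (same (x, y) order)."""
        return self.centers * self.pixel_size_um

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        return {
            "coordinates": "0-based pixels, (x, y) = (column, row)",
            "pixel_size_um": self.pixel_size_um,
            "radius_px": self.radius_px,
            "field_size": list(self.field_size),
            "centers": np.round(self.centers, 4).tolist(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CellMap":
        d = json.loads(Path(path).read_text())
        return cls(
            centers=np.asarray(d["centers"], dtype=float),
            radius_px=float(d["radius_px"]),
            pixel_size_um=float(d["pixel_size_um"]),
            field_size=tuple(d["field_size"]),
        )

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["cell_id", "x_px", "y_px"])
            for i, (x, y) in enumerate(self.centers):
                w.writerow([i, f"{x:.4f}", f"{y:.4f}"])

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        radius_px: float,
        pixel_size_um: float,
        field_size: tuple[int, int],
    ) -> "CellMap":
        """Read a (cell_id, x_px, y_px) table; metadata comes from the caller."""
        centers = []
        with open(path, newline="") as fh:
            r = csv.reader(fh)
            next(r)
            for row in r:
                centers.append((float(row[1]), float(row[2])))
        return cls(np.asarray(centers), radius_px, pixel_size_um, field_size)


@dataclass
class TraceSet:
    """Raw per-cell mean-intensity time series.

    ``traces`` is an ``(n_cells, n_frames)`` matrix; row order matches the
    cell ids of the :class:`CellMap` it was extracted with.
    """

    traces: np.ndarray
    frame_rate: float
    cells: CellMap | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if self.traces.shape[1] < 2:
            raise ValueError("a TraceSet needs at least 2 frames")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("traces contain non-finite values")

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["cell_id"] + [f"f{t}" for t in range(self.n_frames)])
            for i, row in enumerate(self.traces):
                w.writerow([i] + [f"{v:.6g}" for v in row])

    @classmethod
    def from_csv(cls, path: str | Path, frame_rate: float) -> "TraceSet":
        mat = []
        with open(path, newline="") as fh:
            r = csv.reader(fh)
            next(r)  # header
            for row in r:
                mat.append([float(v) for v in row[1:]])
        return cls(np.asarray(mat), frame_rate=frame_rate, source=str(path))


# --------------------------------------------------------------------------
def average_image(movie: np.ndarray) -> np.ndarray:
    """Temporal mean of a ``(frames, height, width)`` stack as float64."""
    movie = np.asarray(movie)
    if movie.ndim != 3 or movie.shape[0] < 1:
        raise ValueError("movie must be a non-empty (frames, h, w) stack")
    return movie.mean(axis=0, dtype=np.float64)


def detect_cells(
    avg_image: np.ndarray,
    radius_px: float,
    min_separation_px: float | None = None,
    threshold_k: float = 3.0,
    pixel_size_um: float = 1.0,
) -> CellMap:
    """Detect cell centers on an averaged fluorescence image.

    The image is band-passed with a matched filter for flat-topped disks of
    the given radius (disk-mean minus a wide Gaussian with sigma
    ``2 * radius``); because the disk average of a disk-shaped cell peaks
    sharply at its center, the local maxima of this response localize
    centers to within a pixel even though the cells themselves have flat
    intensity tops.  A candidate maximum is kept when its averaged-image
    intensity exceeds ``background_median + threshold_k * background_MAD``,
    where the background statistics are sampled from the dim half of the
    averaged image (in a confluent monolayer the inter-cell gaps and any
    denuded lane).  Kept maxima go through greedy minimum-separation
    suppression (brightest first, ties broken by the lexicographically
    smallest ``(y, x)``).  Deterministic: the same image always yields the
    same CellMap; ids are assigned in row-major center order.
    """
    img = np.asarray(avg_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("avg_image must be 2-D")
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1 pixel")
    if min_separation_px is None:
        min_separation_px = 1.5 * radius_px

    rad = int(np.ceil(radius_px))
    yy, xx = np.mgrid[-rad : rad + 1, -rad : rad + 1]
    disk = (xx**2 + yy**2 <= radius_px**2).astype(float)
    disk /= disk.sum()
    band = ndimage.correlate(img, disk, mode="nearest") - ndimage.gaussian_filter(
        img, 2.0 * radius_px
    )
    bg = img[img <= np.median(img)]
    bg_med = float(np.median(bg))
    bg_mad = float(np.median(np.abs(bg - bg_med)))
    # a detection must clear the background both by threshold_k robust
    # noise units and by a 10 % fraction of the image's bright contrast;
    # the latter rejects sub-noise ripples in large cell-free regions of a
    # heavily averaged stack.  The epsilon guards constant images where the
    # only variation is floating-point residue of the filters.
    contrast = float(np.percentile(img, 95)) - bg_med
    thr = (
        bg_med
        + max(threshold_k * bg_mad, 0.1 * contrast)
        + 1e-6 * (np.ptp(img) + 1.0)
    )

    local_max = band >= ndimage.maximum_filter(band, size=3, mode="nearest")
    rows, cols = np.nonzero(local_max & (band > 0) & (img > thr))
    if rows.size == 0:
        return CellMap(
            np.zeros((0, 2)), radius_px, pixel_size_um, tuple(img.shape)
        )

    intens = band[rows, cols]
    order = np.lexsort((cols, rows, -intens))  # intensity desc, then (y, x)
    kept: list[tuple[float, float]] = []
    min_sep2 = min_separation_px**2
    for k in order:
        x, y = float(cols[k]), float(rows[k])
        if all((x - kx) ** 2 + (y - ky) ** 2 >= min_sep2 for kx, ky in kept):
            kept.append((x, y))
    centers = np.asarray(kept)
    centers = centers[np.lexsort((centers[:, 0], centers[:, 1]))]
    return CellMap(centers, radius_px, pixel_size_um, tuple(img.shape))


def import_cells(
    roi_file: str | Path,
    field_size: tuple[int, int] | None = None,
    radius_px: float | None = None,
    pixel_size_um: float | None = None,
) -> CellMap:
    """Load manually drawn circular ROIs from a JSON file.

    The file may either carry full metadata (the format written by
    :meth:`CellMap.to_json`) or be a bare list of ``[x, y]`` centers, in
    which case ``field_size``, ``radius_px`` and ``pixel_size_um`` must be
    supplied from the movie metadata.  Out-of-field centers raise an error
    naming the offending ROI.
    """
    d = json.loads(Path(roi_file).read_text())
    if isinstance(d, list):
        if field_size is None or radius_px is None or pixel_size_um is None:
            raise ValueError(
                "a bare center list needs field_size, radius_px and "
                "pixel_size_um from the movie metadata"
            )
        centers = np.asarray(d, dtype=float)
    else:
        centers = np.asarray(d["centers"], dtype=float)
        radius_px = float(d.get("radius_px", radius_px))
        pixel_size_um = float(d.get("pixel_size_um", pixel_size_um))
        field_size = tuple(d.get("field_size", field_size))
    return CellMap(centers, radius_px, pixel_size_um, tuple(field_size))


def extract_traces(
    movie: np.ndarray, cells: CellMap, frame_rate: float = 2.0
) -> TraceSet:
    """Mean intensity over each cell's disk, per frame.

    Disks clipped at the field border use only in-field pixels; a disk with
    no in-field pixel at all is an error.
    """
    movie = np.asarray(movie)
    if movie.ndim != 3:
        raise ValueError("movie must be (frames, h, w)")
    if cells.n_cells == 0:
        raise ValueError("CellMap is empty")
    t, h, w = movie.shape
    if (h, w) != tuple(cells.field_size):
        raise ValueError(
            f"movie frames {h}x{w} do not match CellMap field "
            f"{cells.field_size[0]}x{cells.field_size[1]}"
        )
    r = cells.radius_px
    traces = np.empty((cells.n_cells, t), dtype=float)
    for i, (cx, cy) in enumerate(cells.centers):
        x0 = max(0, int(np.floor(cx - r)))
        x1 = min(w, int(np.ceil(cx + r)) + 1)
        y0 = max(0, int(np.floor(cy - r)))
        y1 = min(h, int(np.ceil(cy + r)) + 1)
        if x0 >= x1 or y0 >= y1:
            raise ValueError(f"cell {i} disk lies entirely outside the field")
        yy, xx = np.mgrid[y0:y1, x0:x1]
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        if not mask.any():
            raise ValueError(f"cell {i} disk covers no in-field pixel")
        ys, xs = np.nonzero(mask)
        traces[i] = movie[:, ys + y0, xs + x0].mean(axis=1)
    return TraceSet(traces, frame_rate=frame_rate, cells=cells)
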