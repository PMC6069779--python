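"""Wound-relative distance bands and percentage of responsive cells (%RC).

A wounded field of view is partitioned by distance from the wound polygon:
cells inside the polygon form the "wound" zone (meaningful for healed
wounds, where cells have repopulated the lane), and cells outside fall into
concentric bands of a configurable width (default 50 um, within the 40-60 um
range used for adjacency to a scratch wound): area1, area2, area3, then
"beyond".  A recording without a wound is a single "control" zone.

%RC in a zone is the percentage of its cells that show at least one
detected calcium transient during the recording.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .detection import CellMap

ZONE_ORDER = ["wound", "area1", "area2", "area3", "beyond", "control"]


@dataclass
class WoundGeometry:
    """A simple polygon delimiting the denuded / healed region, in pixels."""

    polygon: Polygon
    pixel_size_um: float

    def __post_init__(self) -> None:
        if not isinstance(self.polygon, Polygon):
            self.polygon = Polygon(self.polygon)
        if (not self.polygon.is_valid) or self.polygon.area <= 0:
            raise ValueError("wound polygon must be simple with area > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @classmethod
    def from_vertices(
        cls, vertices, pixel_size_um: float
    ) -> "WoundGeometry":
        return cls(Polygon(vertices), pixel_size_um)

    @classmethod
    def from_json(cls, path: str | Path, pixel_size_um: float) -> "WoundGeometry":
        return cls.from_vertices(json.loads(Path(path).read_text()), pixel_size_um)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(np.asarray(self.polygon.exterior.coords).tolist())
        )


@dataclass
class ZonePartition:
    """Zone label and wound-edge distance for every cell id."""

    labels: dict[int, str]
    distances_um: dict[int, float]
    band_width_um: float

    def to_frame(self) -> pd.DataFrame:
        ids = sorted(self.labels)
        return pd.DataFrame(
            {
                "cell_id": ids,
                "zone": [self.labels[i] for i in ids],
                "distance_um": [self.distances_um[i] for i in ids],
            }
        )

    def cells_in(self, zone: str) -> list[int]:
        return [i for i, z in self.labels.items() if z == zone]


@dataclass
class RCResult:
    """Per-zone responsive-cell statistics for one recording."""

    table: pd.DataFrame  # zone, n_cells, n_responsive, rc_percent
    recording_id: str = ""

    def rc(self, zone: str) -> float:
        row = self.table[self.table["zone"] == zone]
        if row.empty:
            raise KeyError(f"no such zone: {zone}")
        return float(row["rc_percent"].iloc[0])


def assign_zones(
    cells: CellMap,
    wound: WoundGeometry,
    band_width_um: float = 50.0,
    n_bands: int = 3,
) -> ZonePartition:
    """Label every cell wound / area1..areaN / beyond by center position.

    Membership is decided by the cell center: inside the polygon -> wound;
    otherwise the Euclidean distance d from the center to the polygon
    boundary buckets into band ``ceil(d / band_width_um)`` (a center exactly
    on the boundary counts as area1).  Bands past ``n_bands`` are "beyond".
    """
    if not 40.0 <= band_width_um <= 60.0:
        warnings.warn(
            f"band width {band_width_um} um is outside the conventional "
            "40-60 um range",
            stacklevel=2,
        )
    if band_width_um <= 0:
        raise ValueError("band_width_um must be positive")
    poly = wound.polygon
    labels: dict[int, str] = {}
    dists: dict[int, float] = {}
    for i, (x, y) in enumerate(cells.centers):
        p = Point(x, y)
        if poly.contains(p):
            labels[i] = "wound"
            dists[i] = 0.0
            continue
        d_um = poly.exterior.distance(p) * cells.pixel_size_um
        dists[i] = d_um
        band = max(1, int(np.ceil(d_um / band_width_um)))
        labels[i] = f"area{band}" if band <= n_bands else "beyond"
    return ZonePartition(labels, dists, band_width_um)


def compute_rc(
    partition: ZonePartition | None,
    peaks: pd.DataFrame,
    cells: CellMap,
    recording_id: str = "",
) -> RCResult:
    """Percentage of responsive cells per zone.

    A cell is responsive iff it has at least one row in the peak table.
    ``partition=None`` treats the whole field as a single "control" zone
    (a non-wounded recording).  A zone with zero cells is reported with
    ``rc_percent = NaN`` rather than 0.
    """
    responsive = set(peaks["cell_id"].unique()) if len(peaks) else set()
    if partition is None:
        labels = {i: "control" for i in range(cells.n_cells)}
    else:
        labels = partition.labels
    rows = []
    zones = [z for z in ZONE_ORDER if z in set(labels.values())]
    for zone in zones:
        ids = [i for i, z in labels.items() if z == zone]
        n = len(ids)
        n_resp = sum(1 for i in ids if i in responsive)
        rc = 100.0 * n_resp / n if n else float("nan")
        if n == 0:
            warnings.warn(f"zone {zone} has no cells; %RC undefined", stacklevel=2)
        rows.append(
            {"zone": zone, "n_cells": n, "n_responsive": n_resp, "rc_percent": rc}
        )
    return RCResult(pd.DataFrame(rows), recording_id=recording_id)
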