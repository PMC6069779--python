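"""Recovery studies on synthetic presets.

Each function simulates recordings from a named preset, runs the full
analysis pipeline on the rendered movies (detection, extraction, trace
processing, peak calling, and the relevant downstream stage), and returns
the summary statistic the corresponding experimental condition reports.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np

from .pipeline import analyze_movie
from .synthetic import preset, simulate_recording, simulate_wound_series
from .wave import WaveParams, build_wave
from .wound import healing_metrics
from .zones import assign_zones, compute_rc


def _analyze(rec):
    p = preset(rec.preset_name)
    return analyze_movie(
        rec.movie,
        radius_px=p.monolayer.cell_radius_um / p.monolayer.pixel_size_um,
        pixel_size_um=p.monolayer.pixel_size_um,
        frame_rate=p.kinetics.frame_rate,
    )


def wave_sizes(preset_name: str, seeds: Iterable[int]) -> list[int]:
    """Detected induced-wave member counts, one per simulated recording."""
    p = preset(preset_name)
    out = []
    for seed in seeds:
        rec = simulate_recording(p, seed)
        res = _analyze(rec)
        result = build_wave(res.cells, res.peaks, rec.stim_xy, WaveParams())
        out.append(result.n_cells)
    return out


def zone_rc(
    preset_name: str,
    seeds: Iterable[int],
    zone: str,
    wounded: bool = True,
    band_width_um: float = 50.0,
) -> list[float]:
    """Per-recording %RC of one zone (``zone="control"`` with
    ``wounded=False`` analyzes the paired non-wounded field)."""
    p = preset(preset_name)
    out = []
    for seed in seeds:
        rec = simulate_recording(p, seed, wounded=wounded)
        res = _analyze(rec)
        if wounded and rec.wound is not None:
            partition = assign_zones(
                res.cells, rec.wound, band_width_um=band_width_um
            )
        else:
            partition = None
        rc = compute_rc(partition, res.peaks, res.cells)
        out.append(rc.rc(zone))
    return out


def healing_time(preset_name: str) -> float:
    """Healing time (h) of the deterministic preset wound series."""
    series = simulate_wound_series(preset(preset_name))
    return healing_metrics(series, closure_epsilon=0.0).healing_time_h


def derived_seeds(base_seed: int, offset: int, n: int) -> list[int]:
    """n distinct per-recording seeds derived from one base seed."""
    return [(base_seed * 1000 + offset + i) % (2**31) for i in range(1, n + 1)]
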