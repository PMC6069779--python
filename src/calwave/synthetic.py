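"""Ground-truthed synthetic recordings of calcium activity and wound closure.

The generator emulates the study conditions the analysis stages assume:

* a jittered-grid monolayer of fixed-radius circular cells;
* per-cell baseline fluorescence with single-exponential photobleaching,
  additive Gaussian pixel noise, and spontaneous transients whose
  per-zone responsive fractions are configurable;
* a mechanically induced intercellular wave propagating radially from a
  stimulated cell at constant speed, so that neighbouring members peak
  within the lag window the wave detector expects;
* scripted wound-closure mask series with a linear (or stalled) profile.

Every injected event is returned in a ground-truth table, so the whole
pipeline (detection, trace processing, peak calling, zoning, wave
reconstruction, healing kinetics) can be verified end to end without any
recorded data.  Named presets, stored as versioned YAML data files, carry
the parameter sets of the study's experimental conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .detection import CellMap
from .wound import WoundSeries
from .zones import WoundGeometry, assign_zones

_TWO31 = 2**31


# ------------------------------------------------------------------ specs
@dataclass(frozen=True)
class MonolayerSpec:
    """Jittered-grid monolayer geometry."""

    field_size: tuple[int, int] = (384, 384)  # (height, width) px
    pixel_size_um: float = 1.0
    cell_radius_um: float = 7.0
    packing: float = 2.5  # grid spacing in units of the radius, >= 2
    jitter_sd_um: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.cell_radius_um <= 0:
            raise ValueError("pixel size and cell radius must be positive")
        if self.packing < 2.0:
            raise ValueError("packing must be >= 2.0 (non-overlapping cells)")
        if self.jitter_sd_um < 0:
            raise ValueError("jitter_sd_um must be non-negative")


@dataclass
class KineticsSpec:
    """Per-cell fluorescence kinetics and spontaneous-transient statistics."""

    frame_rate: float = 2.0
    n_frames: int = 600
    baseline_mean: float = 1000.0
    baseline_cv: float = 0.1
    bleach_fraction: float = 0.15  # fraction of baseline lost over the record
    noise_sd: float = 20.0
    background: float = 100.0
    transient_amplitude: float = 1.5  # normalized F/F0 peak height
    transient_amplitude_sd: float = 0.05
    transient_rise_s: float = 4.0
    transient_decay_s: float = 15.0
    responsive_fraction_by_zone: dict[str, float] = field(
        default_factory=lambda: {"control": 0.15}
    )
    event_window_s: tuple[float, float] = (25.0, 255.0)
    mean_extra_events: float = 0.7  # events per responsive cell = 1 + Poisson
    min_event_gap_s: float = 20.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0 or self.n_frames < 2:
            raise ValueError("need frame_rate > 0 and n_frames >= 2")
        if not 0.0 <= self.bleach_fraction < 1.0:
            raise ValueError("bleach_fraction must be in [0, 1)")
        for z, p in self.responsive_fraction_by_zone.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"responsive fraction for {z} outside [0,1]")
        if self.noise_sd < 0 or self.baseline_mean <= 0:
            raise ValueError("invalid noise or baseline parameters")

    @property
    def duration_s(self) -> float:
        return (self.n_frames - 1) / self.frame_rate


@dataclass(frozen=True)
class WaveSpec:
    """A radially propagating induced wave from a stimulation point."""

    origin_xy: tuple[float, float]  # pixel coordinates of the stimulated cell
    max_radius_um: float
    propagation_speed_um_s: float = 12.0
    stim_time_s: float = 40.0
    amplitude: float = 1.6
    participation_p0: float = 1.0  # participation probability at the origin
    participation_decay_um: float | None = None  # e-folding radius, None=flat

    def __post_init__(self) -> None:
        if self.max_radius_um < 0:
            raise ValueError("max_radius_um must be >= 0")
        if self.propagation_speed_um_s <= 0:
            raise ValueError("propagation speed must be positive")
        if not 0.0 <= self.participation_p0 <= 1.0:
            raise ValueError("participation probability outside [0, 1]")

    def per_hop_lag_s(self, cell_size_um: float, multiplier: float = 2.5) -> float:
        """Worst-case peak-time lag between adjacent member cells."""
        return multiplier * cell_size_um / self.propagation_speed_um_s


@dataclass(frozen=True)
class WoundClosureSpec:
    """Scripted closure of a binary wound mask."""

    initial_wound_mask: np.ndarray
    closure_time_h: float
    frame_interval_h: float = 1.0
    closure_profile: str = "linear"  # "linear" | "stalled"
    stall_fraction: float = 0.25  # residual area fraction for "stalled"
    follow_up_h: float | None = None

    def __post_init__(self) -> None:
        if self.closure_time_h <= 0:
            raise ValueError("closure_time_h must be positive")
        if self.frame_interval_h <= 0:
            raise ValueError("frame_interval_h must be positive")
        if self.closure_profile not in ("linear", "stalled"):
            raise ValueError("closure_profile must be 'linear' or 'stalled'")


# ------------------------------------------------------- monolayer geometry
def generate_monolayer(spec: MonolayerSpec) -> CellMap:
    """Place non-overlapping cell centers on a jittered grid.

    Grid spacing is ``packing * radius``; each node is displaced by
    truncated Gaussian jitter whose clip radius guarantees the minimum
    pairwise center distance stays above one cell radius.  Deterministic
    for a given seed; centers are returned in row-major order.
    """
    h, w = spec.field_size
    px = spec.pixel_size_um
    r_px = spec.cell_radius_um / px
    spacing = spec.packing * r_px
    sd_px = spec.jitter_sd_um / px
    clip = min(3.0 * sd_px, max(0.0, (spacing - r_px) / 2.0 - 0.5))
    margin = r_px + clip
    xs = np.arange(margin, w - 1 - margin + 1e-9, spacing)
    ys = np.arange(margin, h - 1 - margin + 1e-9, spacing)
    if xs.size == 0 or ys.size == 0:
        raise ValueError(
            f"field {h}x{w} px too small for any cell of radius "
            f"{r_px:.1f} px at packing {spec.packing}"
        )
    gx, gy = np.meshgrid(xs, ys)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    rng = np.random.default_rng(spec.seed)
    if sd_px > 0:
        jitter = np.clip(
            rng.normal(0.0, sd_px, size=centers.shape), -clip, clip
        )
        centers = centers + jitter
    centers = centers[np.lexsort((centers[:, 0], centers[:, 1]))]
    return CellMap(centers, r_px, px, (h, w))


# ------------------------------------------------------------ event models
def transient_kernel(
    t_s: np.ndarray, rise_s: float, decay_s: float
) -> np.ndarray:
    """Difference-of-exponentials transient, peak-normalized to 1 at t=0.

    ``t_s`` is time relative to the PEAK of the transient (negative during
    the rise).  The underlying shape is
    ``exp(-t/decay) - exp(-t/rise)`` for t >= onset, shifted so its maximum
    sits at t = 0.
    """
    if rise_s <= 0 or decay_s <= rise_s:
        raise ValueError("need 0 < rise_s < decay_s")
    t_peak = math.log(decay_s / rise_s) * rise_s * decay_s / (decay_s - rise_s)
    g_max = math.exp(-t_peak / decay_s) - math.exp(-t_peak / rise_s)
    t = np.asarray(t_s, dtype=float) + t_peak
    out = np.where(
        t > 0, np.exp(-t / decay_s) - np.exp(-t / rise_s), 0.0
    )
    return out / g_max


_EVENT_COLUMNS = [
    "cell_id", "x_px", "y_px", "event_time_s", "event_frame", "amplitude",
    "wave_member", "zone",
]


def _sampled_peak_frame(
    t_event_s: float, kinetics: "KineticsSpec"
) -> int:
    """Frame at which the injected transient actually peaks on the frame grid.

    The continuous kernel peaks exactly at the event time, but the movie is
    sampled at the frame rate, so the rendered maximum lands on the nearby
    frame with the largest sampled kernel value; that frame is what the
    ground-truth table records.
    """
    rate = kinetics.frame_rate
    k0 = int(round(t_event_s * rate))
    lo = max(0, k0 - 3)
    hi = min(kinetics.n_frames - 1, k0 + 3)
    frames = np.arange(lo, hi + 1)
    vals = transient_kernel(
        frames / rate - t_event_s,
        kinetics.transient_rise_s,
        kinetics.transient_decay_s,
    )
    return int(frames[np.argmax(vals)])


def draw_spontaneous_events(
    cells: CellMap,
    kinetics: KineticsSpec,
    rng: np.random.Generator,
    zone_labels: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Sample responsive cells and their transient times and amplitudes.

    Each cell is responsive with its zone's configured probability
    (zones default to "control" everywhere); a responsive cell receives
    ``1 + Poisson(mean_extra_events)`` transients at uniform times within
    the event window, thinned to respect the minimum inter-event gap.
    """
    fractions = kinetics.responsive_fraction_by_zone
    t_lo, t_hi = kinetics.event_window_s
    t_hi = min(t_hi, kinetics.duration_s)
    if t_hi <= t_lo:  # recording shorter than the configured window
        t_lo = 0.25 * t_hi
    rows = []
    for i, (x, y) in enumerate(cells.centers):
        zone = zone_labels.get(i, "control") if zone_labels else "control"
        p = fractions.get(zone, fractions.get("control", 0.0))
        if rng.random() >= p:
            continue
        k = 1 + rng.poisson(kinetics.mean_extra_events)
        times: list[float] = []
        for _ in range(50):
            if len(times) >= k:
                break
            t = float(rng.uniform(t_lo, t_hi))
            if all(abs(t - u) >= kinetics.min_event_gap_s for u in times):
                times.append(t)
        for t in sorted(times):
            amp = max(
                1.25,
                float(
                    rng.normal(
                        kinetics.transient_amplitude,
                        kinetics.transient_amplitude_sd,
                    )
                ),
            )
            rows.append(
                {
                    "cell_id": i, "x_px": x, "y_px": y, "event_time_s": t,
                    "event_frame": _sampled_peak_frame(t, kinetics),
                    "amplitude": amp, "wave_member": False, "zone": zone,
                }
            )
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS)


def draw_wave_events(
    cells: CellMap,
    wave: WaveSpec,
    kinetics: KineticsSpec,
    rng: np.random.Generator,
    zone_labels: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Injected wave membership and peak times.

    Cells within ``max_radius_um`` of the origin participate with
    probability ``p0 * exp(-d / decay)`` (flat ``p0`` by default) and peak
    at ``stim_time + d / speed``, so peak times are non-decreasing with
    distance (and hence with hop count) from the origin.
    """
    h, w = cells.field_size
    ox, oy = wave.origin_xy
    if not (0 <= ox <= w - 1 and 0 <= oy <= h - 1):
        raise ValueError(f"wave origin {wave.origin_xy} outside the field")
    d_um = (
        np.linalg.norm(cells.centers - np.array([ox, oy]), axis=1)
        * cells.pixel_size_um
    )
    rows = []
    for i in np.argsort(d_um):
        d = float(d_um[i])
        if d > wave.max_radius_um:
            break
        p = wave.participation_p0
        if wave.participation_decay_um is not None:
            p *= math.exp(-d / wave.participation_decay_um)
        if p < 1.0 and rng.random() >= p:
            continue
        t = wave.stim_time_s + d / wave.propagation_speed_um_s
        x, y = cells.centers[i]
        zone = zone_labels.get(int(i), "control") if zone_labels else "control"
        rows.append(
            {
                "cell_id": int(i), "x_px": x, "y_px": y, "event_time_s": t,
                "event_frame": _sampled_peak_frame(t, kinetics),
                "amplitude": wave.amplitude, "wave_member": True,
                "zone": zone,
            }
        )
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS)


# --------------------------------------------------------------- rendering
def render_movie(
    cells: CellMap,
    kinetics: KineticsSpec,
    wave: WaveSpec | None = None,
    wound: WoundGeometry | None = None,
    seed: int = 0,
    band_width_um: float = 50.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a 16-bit fluorescence movie plus its ground-truth event table.

    Each cell is drawn as a uniform-intensity disk with a 1-px soft edge;
    its intensity follows ``baseline * bleach(t) * (1 + sum of transients)``
    on top of a constant background, with additive Gaussian pixel noise.
    Identical inputs and seed give a bit-identical movie.
    """
    if cells.n_cells == 0:
        raise ValueError("CellMap is empty")
    rng = np.random.default_rng(seed)
    h, w = cells.field_size
    t_frames = kinetics.n_frames
    rate = kinetics.frame_rate

    zone_labels = None
    if wound is not None:
        zone_labels = assign_zones(cells, wound, band_width_um).labels

    baselines = kinetics.baseline_mean * (
        1.0 + kinetics.baseline_cv * rng.standard_normal(cells.n_cells)
    )
    baselines = np.maximum(baselines, 0.1 * kinetics.baseline_mean)

    events = draw_spontaneous_events(cells, kinetics, rng, zone_labels)
    if wave is not None:
        events = pd.concat(
            [events, draw_wave_events(cells, wave, kinetics, rng, zone_labels)],
            ignore_index=True,
        )

    t_s = np.arange(t_frames) / rate
    if kinetics.bleach_fraction > 0:
        bleach = np.exp(
            math.log(1.0 - kinetics.bleach_fraction) * t_s / t_s[-1]
        )
    else:
        bleach = np.ones(t_frames)

    movie = np.full((t_frames, h, w), kinetics.background, dtype=np.float32)
    by_cell = (
        dict(tuple(events.groupby("cell_id"))) if len(events) else {}
    )
    r = cells.radius_px
    for i, (cx, cy) in enumerate(cells.centers):
        signal = np.ones(t_frames)
        for _, ev in by_cell.get(i, pd.DataFrame()).iterrows():
            signal = signal + (ev["amplitude"] - 1.0) * transient_kernel(
                t_s - ev["event_time_s"],
                kinetics.transient_rise_s,
                kinetics.transient_decay_s,
            )
        intensity = baselines[i] * bleach * signal
        x0 = max(0, int(np.floor(cx - r - 1)))
        x1 = min(w, int(np.ceil(cx + r + 1)) + 1)
        y0 = max(0, int(np.floor(cy - r - 1)))
        y1 = min(h, int(np.ceil(cy + r + 1)) + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dist = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
        weight = np.clip(r + 0.5 - dist, 0.0, 1.0)  # 1-px soft edge
        ys, xs = np.nonzero(weight)
        movie[:, ys + y0, xs + x0] += np.outer(
            intensity, weight[ys, xs]
        ).astype(np.float32)
    if kinetics.noise_sd > 0:
        for f in range(t_frames):  # per-frame draws keep peak memory small
            movie[f] += rng.normal(0.0, kinetics.noise_sd, size=(h, w)).astype(
                np.float32
            )
    np.clip(movie, 0, 65535, out=movie)
    np.rint(movie, out=movie)  # round, not truncate, into the 16-bit range
    events = events.sort_values(
        ["cell_id", "event_time_s"], ignore_index=True
    )
    return movie.astype(np.uint16), events


def render_wound_series(spec: WoundClosureSpec) -> WoundSeries:
    """Scripted wound-closure mask series with timestamps in hours.

    The per-frame wound area follows the requested profile exactly (pixel
    counts are rounded from the analytic schedule).  Pixels heal in order
    of distance from the wound interior, so the lane closes inward from its
    edges, as cells migrate in from the surrounding monolayer.
    """
    mask0 = np.asarray(spec.initial_wound_mask).astype(bool)
    a0 = int(mask0.sum())
    if a0 == 0:
        raise ValueError("initial wound mask is empty")
    # remaining pixels are those deepest inside the wound
    depth = ndimage.distance_transform_edt(mask0)
    ys, xs = np.nonzero(mask0)
    order = np.lexsort((xs, ys, -depth[ys, xs]))
    ys, xs = ys[order], xs[order]

    end = (
        math.ceil(spec.closure_time_h / spec.frame_interval_h)
        * spec.frame_interval_h
    )
    if spec.closure_profile == "stalled":
        end = spec.follow_up_h if spec.follow_up_h else 2.0 * spec.closure_time_h
    times = np.arange(0.0, end + spec.frame_interval_h / 2.0,
                      spec.frame_interval_h)
    masks = np.zeros((times.size, *mask0.shape), dtype=np.uint8)
    for k, t in enumerate(times):
        frac = max(0.0, 1.0 - t / spec.closure_time_h)
        if spec.closure_profile == "stalled":
            frac = max(spec.stall_fraction, frac)
        n = int(round(a0 * frac))
        masks[k, ys[:n], xs[:n]] = 1
    return WoundSeries(times, masks)


# ----------------------------------------------------------------- presets
@dataclass(frozen=True)
class WavePresetSpec:
    mean_cells: float
    rel_sd: float = 0.05  # between-recording SD of the wave extent
    speed_um_s: float = 12.0
    amplitude: float = 1.6
    stim_time_s: float = 40.0


@dataclass(frozen=True)
class WoundPresetSpec:
    kind: str  # "fresh" (denuded lane) | "healed" (repopulated lane)
    lane_width_um: float = 100.0
    lane_center_frac: float = 0.5


@dataclass(frozen=True)
class HealingPresetSpec:
    closure_time_h: float
    frame_interval_h: float = 1.0
    field_size: tuple[int, int] = (384, 384)
    lane_width_px: int = 100
    profile: str = "linear"


@dataclass
class Preset:
    """A named, fully specified simulation configuration."""

    name: str
    kind: str  # "calcium" | "wave" | "healing"
    description: str
    monolayer: MonolayerSpec | None = None
    kinetics: KineticsSpec | None = None
    responsive_sd_by_zone: dict[str, float] = field(default_factory=dict)
    wound: WoundPresetSpec | None = None
    wave: WavePresetSpec | None = None
    healing: HealingPresetSpec | None = None

    @property
    def closure_time_h(self) -> float:
        if self.healing is None:
            raise AttributeError(f"preset {self.name} has no healing schedule")
        return self.healing.closure_time_h


def _preset_dir():
    return resources.files("calwave") / "presets"


def available_presets() -> list[str]:
    return sorted(
        p.name[: -len(".yaml")]
        for p in _preset_dir().iterdir()
        if p.name.endswith(".yaml")
    )


def preset(name: str) -> Preset:
    """Load a named preset from the package's versioned data files."""
    path = _preset_dir() / f"{name}.yaml"
    if not path.is_file():
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(available_presets())}"
        )
    d = yaml.safe_load(path.read_text())
    p = Preset(name=d["name"], kind=d["kind"], description=d.get("description", ""))
    if "monolayer" in d:
        m = d["monolayer"]
        p.monolayer = MonolayerSpec(
            field_size=tuple(m["field_size"]),
            pixel_size_um=m["pixel_size_um"],
            cell_radius_um=m["cell_radius_um"],
            packing=m["packing"],
            jitter_sd_um=m["jitter_sd_um"],
        )
    if "kinetics" in d:
        k = dict(d["kinetics"])
        k["event_window_s"] = tuple(k.get("event_window_s", (25.0, 255.0)))
        k["responsive_fraction_by_zone"] = dict(
            d.get("responsive_fraction_by_zone", {"control": 0.15})
        )
        p.kinetics = KineticsSpec(**k)
    p.responsive_sd_by_zone = dict(d.get("responsive_fraction_sd_by_zone", {}))
    if "wound" in d:
        p.wound = WoundPresetSpec(**d["wound"])
    if "wave" in d:
        p.wave = WavePresetSpec(**d["wave"])
    if "healing" in d:
        hcfg = dict(d["healing"])
        hcfg["field_size"] = tuple(hcfg.get("field_size", (384, 384)))
        p.healing = HealingPresetSpec(**hcfg)
    return p


# ------------------------------------------------------------- simulation
@dataclass
class SimulatedRecording:
    """One rendered recording plus its complete ground truth."""

    movie: np.ndarray
    cells: CellMap
    events: pd.DataFrame
    wound: WoundGeometry | None
    stim_xy: tuple[float, float] | None
    preset_name: str
    seed: int
    responsive_fractions: dict[str, float]
    wave_target_cells: int | None = None

    @property
    def responsive_cell_ids(self) -> set[int]:
        if len(self.events) == 0:
            return set()
        return set(self.events["cell_id"].unique())


def _lane_polygon(mono: MonolayerSpec, wound: WoundPresetSpec):
    """A vertical scratch lane crossing the whole field, as a WoundGeometry.

    The polygon is extended well past the top and bottom borders so that
    cell-to-boundary distances measure the distance to the lane edge, not to
    a polygon corner.
    """
    h, w = mono.field_size
    half_px = wound.lane_width_um / mono.pixel_size_um / 2.0
    cx = wound.lane_center_frac * (w - 1)
    pad = 10.0 * h
    verts = [
        (cx - half_px, -pad), (cx + half_px, -pad),
        (cx + half_px, h + pad), (cx - half_px, h + pad),
    ]
    return WoundGeometry.from_vertices(verts, mono.pixel_size_um)


def simulate_recording(
    p: Preset, seed: int, wounded: bool = True
) -> SimulatedRecording:
    """Generate one full synthetic calcium recording from a preset.

    A recording-level random draw perturbs the per-zone responsive
    fractions (and, for wave presets, the wave extent) around the preset
    means, emulating sample-to-sample variability; the movie itself is then
    rendered deterministically from the derived seed.  ``wounded=False``
    renders the paired control field: same layout, no wound, every cell in
    the "control" zone.
    """
    if p.kinetics is None or p.monolayer is None:
        raise ValueError(f"preset {p.name} does not describe a calcium recording")
    rng = np.random.default_rng(seed)
    mono = replace(p.monolayer, seed=int(rng.integers(_TWO31)))
    cells = generate_monolayer(mono)

    base = p.kinetics.responsive_fraction_by_zone
    fractions = {
        z: float(
            np.clip(
                base[z] + p.responsive_sd_by_zone.get(z, 0.0) * rng.standard_normal(),
                0.002, 0.998,
            )
        )
        for z in base
    }
    if not wounded:
        fractions = {"control": fractions.get("control", 0.15)}
    kin = replace(p.kinetics, responsive_fraction_by_zone=fractions)

    wound_geom = None
    if wounded and p.wound is not None:
        wound_geom = _lane_polygon(mono, p.wound)
        if p.wound.kind == "fresh":  # denuded lane: no cells inside
            from shapely.geometry import Point

            keep = [
                i
                for i, (x, y) in enumerate(cells.centers)
                if not wound_geom.polygon.contains(Point(x, y))
            ]
            cells = CellMap(
                cells.centers[keep], cells.radius_px, cells.pixel_size_um,
                cells.field_size,
            )

    wave_spec = None
    stim_xy = None
    target = None
    if p.wave is not None:
        target = max(
            3, int(round(p.wave.mean_cells * (1.0 + p.wave.rel_sd * rng.standard_normal())))
        )
        h, w = mono.field_size
        center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        d_center = np.linalg.norm(cells.centers - center, axis=1)
        origin = cells.centers[int(np.argmin(d_center))]
        d_um = (
            np.linalg.norm(cells.centers - origin, axis=1) * mono.pixel_size_um
        )
        d_sorted = np.sort(d_um)
        target = min(target, cells.n_cells)
        if target >= cells.n_cells:
            max_radius = float(d_sorted[-1] + 1.0)
        else:
            max_radius = float((d_sorted[target - 1] + d_sorted[target]) / 2.0)
        stim_xy = (float(origin[0]), float(origin[1]))
        wave_spec = WaveSpec(
            origin_xy=stim_xy,
            max_radius_um=max_radius,
            propagation_speed_um_s=p.wave.speed_um_s,
            stim_time_s=p.wave.stim_time_s,
            amplitude=p.wave.amplitude,
        )

    movie, events = render_movie(
        cells, kin, wave=wave_spec, wound=wound_geom,
        seed=int(rng.integers(_TWO31)),
    )
    return SimulatedRecording(
        movie=movie, cells=cells, events=events, wound=wound_geom,
        stim_xy=stim_xy, preset_name=p.name, seed=seed,
        responsive_fractions=fractions, wave_target_cells=target,
    )


def simulate_wound_series(p: Preset) -> WoundSeries:
    """Deterministic wound-closure mask series from a healing preset."""
    if p.healing is None:
        raise ValueError(f"preset {p.name} has no healing schedule")
    h, w = p.healing.field_size
    mask = np.zeros((h, w), dtype=np.uint8)
    x0 = (w - p.healing.lane_width_px) // 2
    mask[:, x0 : x0 + p.healing.lane_width_px] = 1
    return render_wound_series(
        WoundClosureSpec(
            initial_wound_mask=mask,
            closure_time_h=p.healing.closure_time_h,
            frame_interval_h=p.healing.frame_interval_h,
            closure_profile=p.healing.profile,
        )
    )


def save_recording(rec: SimulatedRecording, out_dir: str | Path) -> None:
    """Persist a recording: TIFF movie, ground-truth CSV, config YAML."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "movie.tif", rec.movie)
    rec.events.to_csv(out / "ground_truth_events.csv", index=False)
    rec.cells.to_json(out / "cells_truth.json")
    if rec.wound is not None:
        rec.wound.to_json(out / "wound_polygon.json")
    meta = {
        "preset": rec.preset_name,
        "seed": rec.seed,
        "stim_xy": list(rec.stim_xy) if rec.stim_xy else None,
        "responsive_fractions": rec.responsive_fractions,
        "coordinates": "0-based pixels, (x, y) = (column, row)",
    }
    (out / "recording.yaml").write_text(yaml.safe_dump(meta))
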