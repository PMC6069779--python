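# calwave

Calcium-imaging and scratch-wound analysis for epithelial monolayers, with
a ground-truthed synthetic-recording generator.

Wounding an epithelial monolayer — the motivating system is stem-cell
derived retinal pigment epithelium (RPE) — changes the intracellular
calcium dynamics of the cells around and inside the wound.  Quantifying
that requires a chain of image-analysis steps that are usually re-implemented
ad hoc per lab: extracting per-cell fluorescence traces from a Fluo-4-type
movie, normalizing them to F/F₀ with photobleaching correction, calling
transient peaks, expressing spontaneous activity as the percentage of
responsive cells (%RC) in wound-relative distance bands, reconstructing a
mechanically induced intercellular Ca²⁺ wave as a connected component of
co-firing neighbours, and measuring scratch-wound closure kinetics from a
mask time lapse.  `calwave` packages that chain as a tested library (plus a
thin CLI) for experimentalists and image-analysis people working with
monolayer calcium recordings.

## The models in brief

- **Traces.** Each cell is a fixed-radius circular ROI; its raw trace is
  background-subtracted, smoothed with a centred 5-point moving average,
  and divided by an exponential baseline `b(t)` through robust start/end
  baseline estimates, so quiescent cells sit at F/F₀ ≈ 1.  Peaks are local
  maxima with amplitude ≥ **1.1** (a 10 % rise over baseline).
- **%RC.** Cells partition by distance to the wound polygon into `wound`,
  `area1..3` (bands of 50 µm by default, configurable within 40–60 µm) and
  `beyond`; %RC per zone is the percentage of cells with ≥ 1 peak.
- **Waves.** Two peaked cells are wave-connected iff some pair of their
  peaks differs by **< 4 s** and their centers are **< 2.5 characteristic
  cell sizes** apart; the induced wave is the connected component
  containing the stimulated cell, its spread area the disk-dilated convex
  hull of member centers (`A + P·r + πr²`).
- **Healing.** Wound size is the mask pixel count; healing time is the
  first fully-closed frame's timestamp; speed = initial area / healing
  time.  Cohorts report percent healed and mean ± SEM.
- **Statistics.** Equal-variance unpaired t test and Mann–Whitney U
  (exact for small tie-free samples), α = 0.05, mean ± SEM; plus cell-area
  morphometry from label masks and 2^−ΔΔCt fold changes.

Because live-cell recordings of this kind are rarely shared, the
`calwave.synthetic` module generates movies, wound time-lapses and label
masks with known ground truth (injected transients, wave membership,
closure schedules), and named presets reproduce the emulated study's
condition means.  See `docs/methods.md` for the full model description.

## Worked example

Simulate a freshly wounded immature monolayer, run the full pipeline and
compute %RC per zone:

```python
import calwave as cw

p = cw.preset("9d15min")                       # fresh-scratch condition
rec = cw.simulate_recording(p, seed=1)         # movie + ground truth
res = cw.analyze_movie(rec.movie, radius_px=7.0,
                       pixel_size_um=1.0, frame_rate=2.0)
part = cw.assign_zones(res.cells, rec.wound, band_width_um=50.0)
rc = cw.compute_rc(part, res.peaks, res.cells)
print(f"{res.cells.n_cells} cells detected, {len(res.peaks)} peaks called")
print(rc.table.to_string(index=False))
```

prints

```
316 cells detected, 112 peaks called
 zone  n_cells  n_responsive  rc_percent
area1      115            36   31.304348
area2      118            12   10.169492
area3       83            14   16.867470
```

Reading: the 115 cells within 50 µm of the wound edge (`area1`) are about
twice as responsive (31 %) as the cells farther out — the elevated
spontaneous calcium activity expected next to a fresh wound.  This
recording injected an area-1 responsive fraction of 0.343, so the measured
31.3 % is a faithful read-out within binomial noise; there is no `wound`
row because the fresh scratch is denuded.

The same stages are exposed on the command line
(`calwave detect / extract / peaks / rc / wave / heal / compare /
simulate`); run `calwave --help`.

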