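# Methods

`calwave` analyzes live-cell calcium-imaging recordings and scratch-wound
time lapses of epithelial monolayers (the motivating system is stem-cell
derived retinal pigment epithelium, RPE), and ships a synthetic-recording
generator that makes every analysis stage verifiable end to end.  This note
documents the models, the defaults and why they were chosen, and what the
synthetic data does and does not emulate.

## Trace model and processing chain

Cells are approximated as fixed-size circles.  Centers are detected on the
temporally averaged fluorescence image; the per-cell signal is the mean
intensity over the circular ROI at every frame (2 frames/s, >= 600 frames
in the emulated recordings).

The raw trace `F_raw(t)` is processed as:

1. **Background**: one scalar per movie is subtracted (auto mode: 5th
   percentile of the averaged image, which samples cell-free or dimmest
   pixels).  Values are floored at a small positive constant so later
   normalization stays defined for degenerate ROIs.
2. **Smoothing**: centered 5-point moving average; at the trace edges the
   window shrinks to the available samples, so a constant trace is a fixed
   point and no padding bias is introduced.
3. **Baselines**: robust medians of the first and last window (default 30
   frames = 15 s).  Each window gets one round of transient exclusion —
   frames more than 5 % above the window median are dropped and the median
   recomputed — which protects the estimate from a transient that starts or
   ends inside the window.  A transient occupying most of a window defeats
   a single median iteration; that is a known limitation.
4. **Bleaching + normalization**: the trace is divided by an interpolant
   `b(t)` through the two baselines, anchored at the window centers.  The
   default interpolant is exponential (first-order photophysics: a pure
   exponential decay cancels exactly); a linear interpolant is available via
   `mode="linear"`.  Multiplicative correction was chosen over subtractive
   because bleaching scales the emitted signal; both end baselines map to
   F/F0 ~= 1.
5. **Peak calling**: local maxima of the normalized trace with amplitude
   >= 1.1 (a 10 % rise over baseline; the comparison is inclusive),
   prominence >= 0.05 and separation >= 5 s.  The prominence and separation
   defaults suppress double-counting of noisy shoulders; the recordings the
   defaults were tuned for have per-frame F/F0 noise of ~1 % after
   smoothing, an order of magnitude below the threshold.  A cell is
   *responsive* iff it has at least one called peak.

## Zones and %RC

A wound is a user-supplied simple polygon in pixel coordinates.  Zone
membership is decided by the cell **center**: inside the polygon → `wound`
(meaningful for healed wounds); otherwise the Euclidean distance to the
polygon boundary buckets cells into bands of `band_width_um` (default
50 um, validated against the conventional 40–60 um range): `area1`,
`area2`, `area3`, then `beyond`.  A center exactly on the boundary counts
as `area1`.  Non-wounded recordings form a single `control` zone.
`%RC = 100 * n_responsive / n_cells` per zone; a zone with no cells is
reported as NaN, never 0.

## Induced-wave reconstruction

Two peaked cells propagate a wave to each other iff the closest pair of
their peak times differs by **less than 4 s** (strict) and their centers
are closer than `2.5` characteristic cell sizes (the middle of the
conventional 2–3 range; characteristic size defaults to the cell diameter,
2 × ROI radius).  The induced wave is the connected component containing
the stimulated cell; a stimulation site given as coordinates resolves to
the nearest cell within one cell size (farther → error rather than a
guess).  Peaked components disconnected from the site are reported as
spontaneous clusters.  Temporal ordering along the wave is *not* enforced —
the rule is purely pairwise.  Wave area defaults to the convex hull of
member centers dilated by the cell radius `r` (exact Minkowski sum:
`A + P·r + πr²`; a single member gives `πr²`); the union-of-disks area is
available behind a flag.

## Wound-closure kinetics

Input is a series of binary wound masks with strictly increasing timestamps
in hours (1–3 h sampling emulated).  Wound size is the mask pixel count;
healing time is the timestamp of the first frame with area <=
`closure_epsilon` (default 0) — no interpolation, so the resolution equals
the imaging interval; healing speed is initial area (px) divided by healing
time (h), defined only for healed samples.  Cohort summaries report percent
healed over all samples of a condition (nearest-integer rounding in the
report, full precision in the table) while time/speed statistics use only
healed samples with intact substrate coating.

## Statistics

Classical equal-variance two-sample t test (two-sided; Welch behind a
flag) for approximately normal quantities; two-sided Mann–Whitney U for
wave counts and areas, exact for n_a+n_b <= 20 without ties, otherwise the
normal approximation with tie and continuity corrections.  Significance at
α = 0.05, no multiple-testing correction by default (a Holm option exists).
Summaries are mean ± SEM (sd/√n, ddof=1; undefined at n = 1).  Ancillary
operations: per-cell areas from integer label masks (px and um², with
area_um² = px · pixel_size²) and the 2^−ΔΔCt fold change for qPCR.

## The synthetic generator

The generator's defaults are the emulated study conditions:

- **Monolayer**: jittered grid, spacing 2.5 × radius, truncated Gaussian
  jitter (sd 1.5 um, clipped so the minimum pairwise distance always
  exceeds one radius).  Default geometry: 384×384 px at 1 um/px with
  7 um cell radius (~440 cells/field).  No numeric cell size is asserted as
  a literature value; 14 um diameter was chosen to be consistent with
  epithelial cell areas of a few hundred um², and both radius and field are
  preset parameters.
- **Rendering**: each cell is a uniform disk with a 1-px soft edge;
  intensity = per-cell baseline (CV 10 %) × single-exponential bleach
  (15 % loss over the recording) × (1 + Σ transients), on a constant
  background of 100, plus additive Gaussian pixel noise (sd 20 at baseline
  1000), rounded into 16 bits.  Identical spec + seed gives a bit-identical
  movie.
- **Transients**: difference of exponentials (rise 4 s, decay 15 s,
  ~30–40 s total duration, typical of epithelial calcium transients),
  peak-normalized so the configured amplitude is the F/F0 peak height
  (default 1.5 ± 0.05, floored at 1.25).  Responsive cells are drawn per
  zone with the configured probability; each gets 1 + Poisson(0.7) events
  at uniform times inside an event window that avoids the baseline-
  estimation windows, with a 20 s minimum gap.  The ground-truth table
  records, per event, the frame at which the *sampled* transient peaks.
- **Induced wave**: members peak at `stim_time + d/speed` (12 um/s, so
  adjacent members always lag well under the 4 s rule at the default
  connectivity distance), with amplitude 1.6.  Wave presets draw a
  per-recording target extent (5 % relative SD around the condition mean)
  and set the participation radius at the distance of the target-th nearest
  cell, so the injected membership count is exact.  Spontaneous incidence
  in wave presets is kept low (5 %) and the spontaneous window starts after
  the wave has finished: spontaneous activity and stimulated waves were
  separate acquisitions in the emulated protocol, and this keeps the
  injected membership unambiguous as ground truth.
- **Between-recording variability**: per-zone responsive fractions are
  redrawn once per recording with an SD of half the condition's reported
  SEM.  Full SEM-scale dispersion would make small simulated cohorts (4–10
  recordings) scatter beyond the recovery tolerances the package tests
  itself against; half-SEM keeps visible sample-to-sample variability while
  the cohort means stay identifiable.
- **Wound closure**: the per-frame area follows the analytic schedule
  exactly (rounded pixel counts); pixels heal in order of the distance
  transform, so the lane closes inward from its edges.  A `stalled` profile
  floors the area at a residual fraction and never reaches zero.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: optical PSF and shot noise, pigmentation and
brightfield texture, fusiform (non-circular) cell shapes, cell migration or
division during a recording, mechanistic wave propagation (ATP diffusion /
gap junctions), anisotropic or geodesic wound distances, and real
phase-contrast wound segmentation (the threshold helper is for synthetic
frames only; real masks are external inputs).

## Numerical choices

- Detection: matched filter = disk-mean (radius r) minus Gaussian (σ = 2r).
  The disk average of a flat-topped disk peaks sharply at its center, which
  localizes to ~0.5 px where a narrow Gaussian band-pass leaves a noise-
  dominated plateau.  Candidates must exceed the background median + 3 MAD
  of the dim half of the averaged image *and* a 10 % bright-contrast floor
  (heavy temporal averaging otherwise lets sub-noise ripples in cell-free
  regions through).  Greedy suppression at 1.5 × radius keeps the brightest
  candidate, ties broken by smallest (y, x); ids are row-major.
- Strictness: the 4 s wave lag and the distance cutoff are strict (<); the
  1.1 peak threshold is inclusive (>=).
- Degenerate statistics: zero-variance t with equal means → p = 1; with
  unequal means → error; all-tied Mann–Whitney → p = 1.
- Problem sizes: presets use 384×384 px fields (~440 cells) and 600-frame
  movies; recovery studies run 10 recordings per wave condition and 8/4
  fields per %RC condition, matching the emulated cohort sizes.

## Known limitations

- The two-baseline bleach model cannot represent non-exponential bleaching
  or focus drift; only endpoints constrain the interpolant.
- %RC and wave statistics are computed on detected cells; detection misses
  (<1 % at preset SNR) enter both numerator and denominator and are
  unbiased with respect to responsiveness, but heavily overlapping or
  fusiform cells require imported manual ROIs.
- Healing time has frame-interval resolution by design; sub-interval
  interpolation is deliberately not performed.
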