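# Methods

## The charge model

The simulator formalizes the standard qualitative picture of specimen
charging in secondary-electron SEM of insulators as three linear processes
on a pixel grid:

1. **Deposition.** Every probe visit deposits a fixed charge
   `q0 = I·t_dwell / e` at the visited pixel (3.93 electrons at 6.3 pA and
   100 ns). The probe FWHM (~2 nm) is below the pixel size (6.34 nm), so
   sub-pixel spreading is ignored.
2. **Dissipation.** Between visits the charge field `C` relaxes by isotropic
   lateral diffusion (`∂C/∂t = D ∇²C`, explicit 5-point stencil with
   zero-flux boundaries) and by exponential leak to ground with a per-pixel
   time constant, `C ← C·exp(−dt/τ(x,y))`. This is the simplest model
   consistent with charge that "dissipates uniformly in all directions" at a
   material-dependent rate.
3. **Detection.** The recorded intensity is the secondary-electron yield
   attenuated exponentially by the locally smoothed charge,
   `gain·η(x,y)·exp(−α·C̃) + offset + noise`, with `C̃` the charge field
   smoothed by a Gaussian of width `sigma_local_px` (default 3 px).
   Accumulated charge therefore darkens the image — the dominant artefact on
   vitrified samples; bright flashes are available through an optional
   discharge model (threshold crossing emits a spike and resets the local
   charge), off by default.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `q0_electrons` | 3.93 e⁻ | charge per visit (6.3 pA × 100 ns) |
| `D_px2_per_ns` | 1×10⁻⁵ px²/ns | lateral diffusivity |
| `alpha` | 0.5 | signal attenuation per smoothed electron |
| `sigma_local_px` | 3 px | width of the charge-influence smoothing |
| `noise_std` | 1200 counts | additive detector noise per visit |
| `detector_gain/offset` | 20000 / 2000 | yield→counts mapping (int16 range) |
| `batch_visits` | one line/pass | dissipation-update batching interval |
| `drift_step_px` | 0 (0.3 in the comparison experiment) | random-walk drift std per frame-scan time |

`alpha`, `D` and the phantom's leak times are **calibration constants**, not
measured values: the literature establishes which structures charge and which
scan strategies suffer, not material resistivities. They were chosen once so
that the physical time ordering is meaningful at desk scale (see below) and
are recorded here and in the config defaults.

### Why the calibration works

The revisit interval of spatial neighbours is ~`t_dwell` (raster, fast axis),
~`nx·t_dwell` (raster, slow axis; 25.6 µs at 256 px), and ~one sub-lattice
pass (~0.73 ms at 256² and skip 2) for interleaving. Charging centres are
therefore emulated with leak times *between* the raster and interleaved
revisit scales: lipid-droplet discs 150 µs (100× background), membranes
30 µs, and poorly grounded background patches ~500 µs. Raster scans revisit
neighbours long before these regions have drained and accumulate a locally
smoothed charge of order 1–2 electrons (30–80 % signal loss); by the time an
interleaved pass returns, the same charge has decayed by e⁻² … e⁻⁶ and the
image stays clean. The well-grounded background (1.5 µs) drains between
lines for every strategy.

## The synthetic cell specimen

The `cell` preset emulates a vitrified cytoplasm at ~6 nm pixels: a textured
background (yield 0.5 ± 0.05, grain correlation 2 px), ≥3 high-yield
poorly-draining discs (lipid droplets, yield 0.85), an equal number of
electron-dense compartments (yield 0.15), ≥5 thin anti-aliased membranes of
alternating bright/dark contrast (0.7 / 0.3), smooth poorly grounded
background patches (~20 % of the area, leak ×333), and two kinds of tiny
intensity pins — near-black fissures (yield 0.02) and bright contamination
specks (0.98). Every structure is recorded in the ground-truth label map.

Two generator choices deserve explanation, because they exist to make the
histogram charging metric well-posed rather than to imitate specific
organelles:

* **Intensity pins.** The 8-bit conversion rescales by the stack-global
  min/max. Without features pinning both ends of the intensity range, the
  extremes are set by noise tails and by the single most-charged pixel, so
  the conversion scale itself would depend on the acquisition strategy and
  `|mean − 127|` would no longer measure charging. The fissures and specks
  (≈0.4 % of pixels, symmetric about the 0.5 background) fix the scale; they
  stand in for the cracks, holes and surface contamination that real
  acquisitions contain.
* **Balanced bright/dark areas.** Disc and dark-compartment areas, and
  bright/dark membranes, are balanced so the artefact-free histogram centres
  at ≈127–130. Charging then moves the mean monotonically *down*, as
  observed on real data.

The generator does **not** emulate: 3-D topography and milling artefacts
(curtaining), energy-dependent yield physics, detector nonlinearity, or the
morphological richness of real organelles. Passing tests therefore show that
the *method* (pattern timing, processing pipeline, metrics) behaves
correctly under the modelled charging physics — not that any particular real
specimen will charge by a given amount.

The `flyback_test` preset plants a left band of configurable width whose
columns are displaced by a smoothly decaying, line-to-line phase-advancing
settling oscillation, with the accompanying probe-velocity error imprinted
as intensity ripples. The imprint gains contrast toward the band edge so
that, under the reference estimator settings (σ = 7 blur, which erodes a
one-sided texture edge by about σ/2 while extending its skirt), the apparent
extent matches the planted width.

## The strategy-comparison experiment

`run_strategy_comparison` builds fluence-matched acquisitions (default
schedules 100 ns×100, 500 ns×20, 1000 ns×10 — identical dwell×repetitions
product, hence identical fluence to machine precision) for raster line
integration (with the 70 µs flyback settling delay that instrument-side line
integration imposes), raster frame integration and interleaved frame
integration (skip 2), then runs the paper-style pipeline: 8-bit conversion
(stack-global), flyback crop (64 px scaled from a 2048-wide frame), centred
analysis crop (1920 scaled), patch alignment for frame-integrated stacks,
mean integration, and the QC metrics. Specimen drift is a continuous random
walk (std 0.3 px per frame-scan time); frame-integrated stacks are
registered, while line integration accrues drift per line group — the
uncorrectable intra-frame drift that tears vertical edges row-to-row and,
together with line-local charge accumulation, produces its characteristic
fast-axis streaking.

At the desk-scale default (256², five seeds, one 100 ns×100 schedule,
~7 min on one CPU) interleaved frame integration has the smallest charging
deviation and raster line integration the largest anisotropy index in every
seed. Problem sizes in the tests and in `scripts/acceptance.py` use this
256² grid; larger grids (to 2048²) are supported.

The built-in fallback segmenter (mean filter → Otsu → connected components)
responds to charging artefacts by picking *spurious* high-complexity
components, unlike a learned segmenter which under-picks on corrupted
images; the object/complexity ratios normalised to interleaved frame
integration are reported but their direction should not be compared with
learned-segmenter results.

## Numerical choices

* **Diffusion sub-stepping.** The explicit stencil is sub-stepped at
  `D·dt ≤ 0.2 px²`, strictly inside the 0.25 stability limit so the
  checkerboard mode is damped rather than neutrally stable. The flux-form
  stencil conserves total charge to rounding (tested at 10⁻⁹ relative with
  infinite leak time).
* **Batching.** Dissipation is applied once per scan line / sub-lattice pass
  (`batch_visits=None`) with exact elapsed-time accounting. Three
  corrections keep batching a numerical convenience rather than a model
  change: deposits are credited with `exp(+j·t_dwell/τ)` for their
  within-block age (leak is linear, so this is exact per deposit); detection
  sees the block's own earlier deposits through an exact causal kernel sum,
  including the clamped-edge inflation of the smoothing near image borders;
  and the pre-existing smoothed field is aged per visit with the
  charge-weighted mean leak factor of its contributors (exact for locally
  uniform leak, first-order across leak-time boundaries). On a homogeneous
  64² specimen, per-visit and per-line updates agree to ≤2.4 % in charging
  deviation; across the sharp leak-time boundaries of the cell preset the
  residual image difference is ~3 % RMS.
* **Denormal flushing.** Leaked-away charge is flushed to zero below 10⁻²⁸⁰
  electrons; subnormal arithmetic would otherwise dominate the run time.
* **Alignment.** Reference = first frame (running mean by flag); integer
  shifts recovered exactly on noise-free stacks, sub-pixel shifts to 0.1 px
  by upsampled cross-correlation; patch shift fields interpolated
  bilinearly; resampling uses reflection padding. A 1×1 patch grid gives
  rigid alignment; grids are coarsened automatically on small images so
  patches stay ≥16 px.
* **Thresholds.** The flyback estimator defaults to the histogram-valley
  (`threshold_minimum`) binarization, with Otsu and fixed-value overrides;
  frames where thresholding fails are dropped and the per-frame extents are
  pooled by median (the failure mode seen on real data produces outliers).
* **Conventions.** Coordinates are 0-based, x = column = fast axis; all
  times integer nanoseconds; sub-lattice offsets are enumerated x-major
  (the published schematic's ordering is colour-coded only, so either
  enumeration is defensible); component perimeters use crack-edge length,
  which is exact for axis-aligned rectangles (a 10×10 square scores
  40²/100 = 16); components are 8-connected; quadrants are median-centred
  with on-median points excluded; t-tests are pooled-variance by default
  with Welch by flag.

## Limitations

* The charge model is two-dimensional and linear; it ignores charge
  injection depth, field-assisted beam deflection and Monte-Carlo trajectory
  physics, and its constants are calibrated, not measured.
* `|mean − 127|` is only a charging measure when the artefact-free histogram
  is centred; the generator arranges this, but arbitrary real data need the
  detector offset/gain set per dataset, as in practice.
* Line-integration drift accrual per line group extrapolates the per-frame
  drift specification to a pattern with a single output frame.
* The one-sided causal smoothing reach (±4σ) limits simulated streak length;
  real streaks can extend much further.
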