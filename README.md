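# leapscan

Scan-pattern engineering and charging QC for secondary-electron imaging of
vitrified biological specimens.

Serial FIB/SEM imaging of frozen-hydrated cells and tissue is routinely
limited by specimen charging: lipid droplets, myelin stacks and degradative
compartments drain beam-deposited charge poorly and imprint dark streaks and
patches on the images. An interleaved ("leapfrog") scan visits a sub-lattice
of pixels per pass — skip two in x, return and skip two in y — so that
spatial neighbours are revisited only after a long interval during which the
local charge can dissipate. `leapscan` implements this idea end to end at
desk scale:

* **Scan patterns** — timed raster (line or frame integration) and
  interleaved visit sequences, validation, neighbour-revisit timing, ASCII
  coordinate export for programmable scan engines, and electron-fluence
  arithmetic (`I·t·R / (e·a²)` in e⁻/Å²).
* **Phantoms** — synthetic specimen maps (secondary-electron yield, per-pixel
  charge-leak time, ground-truth labels) with cell-like, myelin and
  flyback-test presets.
* **Charge simulator** — point deposition per visit, isotropic lateral
  diffusion plus exponential leak to ground, and a detector whose signal is
  the yield attenuated exponentially by the locally smoothed charge:
  `gain · η(x,y) · exp(−α·C̃) + offset + noise`.
* **Frame processing** — 16-bit→8-bit conversion (stack-global min/max),
  flyback cropping, centred analysis crops, patch cross-correlation
  alignment (5×5 patches, 20 % overlap), integration, box filtering.
* **Quality metrics** — histogram charging metric (|mean − 127| of the 8-bit
  histogram), flyback-extent estimation (Gaussian σ=7 → Sobel → automatic
  threshold → rightmost foreground column), object count and shape
  complexity (Σ P²/A over labelled components, crack-edge perimeter), a
  streak anisotropy index, and the quadrant count ratio with two-sample /
  one-sample t-tests.
* **Experiment driver** — the fluence-matched strategy comparison
  (raster-LI, raster-FI, interleaved-FI at 100 ns×100, 500 ns×20,
  1000 ns×10) with per-seed verdicts.

## Worked example

```python
import leapscan as ls

# fluence of the reference schedule: 6.3 pA, 100 ns x 100 reps, 6.34 nm pixels
f = ls.compute_fluence(ls.FluenceSpec(6.3, 100, 100, 6.34))
print(f"{f:.4f} e-/A^2")                       # 0.0978 e-/A^2  (~1e-1)

# how much longer neighbours get to dissipate under interleaving (7x7 grid)
r = ls.make_raster_pattern(7, 7, 100)
i = ls.make_interleaved_pattern(7, 7, 2, 2, 100)
print(ls.min_neighbour_interval(r, 1))          # 100   (one dwell time)
print(ls.min_neighbour_interval(i, 1))          # 400   (4x longer)

# the in-silico strategy comparison on a 256x256 synthetic cell
cfg = ls.ExperimentConfig(schedules=[(100, 100)], seeds=[0, 1, 2, 3, 4])
res = ls.run_strategy_comparison(cfg)           # ~7 min on one CPU
print(res.summary["interleaved_fi_win_fraction"])            # 1.0
print(res.summary["mean_deviation_by_strategy"])
# {'interleaved_fi': 2.01, 'raster_fi': 9.24, 'raster_li': 11.55}
```

The fluence matches the nominal 10⁻¹ e⁻/Å² of the reference acquisition
conditions. In the simulated comparison, interleaved frame integration keeps
the 8-bit histogram mean closest to the 127 mid-range in every seed (its
images average ≈121–128 grey levels, against ≈109–124 for the raster
strategies, whose charging drags the mean down), and raster line integration
shows the largest streak anisotropy — the orderings observed on real
cryo-FIB/SEM data.

A `leapscan` command-line tool mirrors the library:

```
leapscan pattern --nx 2048 --ny 2048 --mode interleaved --skip-x 2 --skip-y 2 \
         --dwell-ns 100 --reps 100 --out coords.txt
leapscan phantom  --preset cell --nx 256 --ny 256 --seed 1 --out phantom.tiff
leapscan simulate --phantom phantom.tiff --mode interleaved --reps 100 --out stack.tiff
leapscan process  --in stack.tiff --crop-flyback 8 --center-crop 240 --out image.tiff
leapscan qc       --in image.tiff --report qc.json
leapscan run      --config experiment.yaml
```

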