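# pixroi

Quantification of neutrophil extracellular trap (NET) formation and
degradation from two-channel live-cell time-lapse microscopy.

Neutrophils stimulated into NETosis release webs of decondensed chromatin
(NETs) that a membrane-impermeable DNA dye (Sytox) stains as it becomes
extracellular; a membrane-permeable dye (Hoechst/DAPI) marks every nucleus.
Filmed every 15 minutes for 10–15 hours, each pixel's Sytox time course
tells its fate:

* **netotic** pixels peak and then decay as the NET disperses and is
  degraded by nucleases;
* **necrotic** pixels rise and plateau near their maximum — lysed cells
  whose DNA stays put;
* **background** pixels never leave the noise floor.

`pixroi` classifies every pixel from that trace shape, estimates NET
half-lives from the classified pixels, and counts cells — with a seeded
synthetic video generator providing ground truth for validation.

## Method

For a smoothed Sytox trace the pipeline computes a *background-rescaled*
signal `x̃_t = x_t / b_t`, where `b_t` is the mean intensity over the
common background — the pixels below the per-frame Otsu threshold in every
non-trivial frame, i.e. pixels never part of a cell or a NET. Division by
`b_t` cancels global, per-frame contrast drift. With `d_t = x̃_{t+1} − x̃_t`
the classification rules are, in order:

* **necrotic**: max x̃ > 5, more than 50% of the steps after the trace
  minimum have `d_t > 0`, and the final value exceeds 90% of the maximum;
* **netotic**: max x̃ > 5, more than 50% of the steps after the trace
  maximum have `d_t < 0`, and the final value is below the maximum;
* **background**: otherwise.

Kinetics then work on *raw* smoothed traces of pixels labelled netotic:
1000 sampled pixels are aligned at their peaking times, normalized between
0 (minimal pre-peak value) and 1 (peak), and summarized pointwise by the
median and the 25%/75% quartile curves. The **50%-lifetime** (half-life) and
**80%-lifetime** are the times each curve needs to fall from 1 to 0.5 or
0.2, linearly interpolated between frames; a curve that never reaches a
level is reported censored. The census counts Otsu components of the first
DAPI frame gated to 1000–4000 px (initial cells) and necrotic components
gated to 5000–10000 px; the netotic count is their difference, and the
**net span** divides total netotic coverage by it.

## Worked example

```python
from pixroi import RunConfig, analyze_field
from pixroi.synthetic import random_scene, generate_video

scene = random_scene(n_netotic=3, n_necrotic=2, height=320, width=320,
                     n_frames=61, decay_half_life=360.0, seed=11)
dapi, sytox, truth = generate_video(scene)
res = analyze_field(sytox, dapi, RunConfig())
print(res.counts)
print(f"NET half-life: {res.half_life:.1f} min (true {truth.half_lives[0]:.0f})")
print(f"net span: {res.span.span_per_cell:.0f} px/cell")
```

prints

```
CellCounts(initial_cells=5, necrotic_cells=2, netotic_cells=3)
NET half-life: 372.2 min (true 360)
net span: 2757 px/cell
```

i.e. the census recovers all five seeded cells and their fates, the
half-life of the 6-hour condition is recovered within one frame interval
(15 min), and the per-cell NET extent matches the mean seeded footprint
(2757 px). Estimators (`TemporalSmoother`, `BackgroundRescaler`,
`PixROIClassifier`, `DecayKinetics`) also compose as a scikit-learn
`Pipeline` over `(n_pixels, n_frames)` trace matrices, and a `pixroi`
console script exposes `simulate`, `preprocess`, `classify`, `lifetimes`,
`counts` and `netarea` subcommands for on-disk TIFF/CSV workflows.

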