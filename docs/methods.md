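# Methods

## The measurement problem

A field of view of PMA-stimulated neutrophils is filmed in two channels:
Hoechst/DAPI (membrane-permeable, all nuclei) and Sytox (membrane-
impermeable, extracellular/dead-cell DNA only), one frame every 15 minutes
for 10–15 hours. NET release and degradation are purely kinetic phenomena
at the pixel level: a pixel covered by a NET brightens in Sytox, peaks, and
dims again as nucleases disperse the chromatin, whereas a pixel inside a
lysed (necrotic) cell brightens and stays bright. The package turns that
observation into per-pixel class maps, per-field half-lives and cell
counts.

## Pipeline model and assumptions

1. **Temporal smoothing.** Every pixel trace is convolved with a Gaussian
   (default σ = 1 frame, reflect boundary). Smoothing is temporal only;
   spatial structure is untouched. σ is configurable; the suite exercises
   0.5, 1 and 2.
2. **Common background.** For each frame the Otsu threshold splits
   foreground from background; the common background is the intersection of
   the below-threshold regions over all *non-trivial* frames — pixels that
   were never part of a cell or NET. Averaging each frame over that mask
   gives the scaling curve `b_t`.
   *Triviality.* A frame is trivial when it is spatially constant, when the
   Otsu split leaves <1% of pixels on either side, or when Otsu's
   between-class separability η (between-class variance / total variance, a
   scale-free statistic) is below 0.75. The last rule is what excludes
   frames containing only noise — Otsu on a unimodal histogram splits it
   near the mean (η ≈ 0.64), and intersecting dozens of such half-masks
   would annihilate the background. If *no* frame is non-trivial but the
   video is not constant, the whole field is treated as background with a
   warning: a video with no detectable foreground is all background, and
   this keeps empty fields analyzable. A fully constant video is an error.
3. **Background rescaling.** `x̃_t = x_t / b_t`. Any per-frame multiplicative
   drift `s_t > 0` applied to the video multiplies `b_t` equally and cancels
   (Otsu thresholds and the η statistic are scale-covariant, so the mask is
   unchanged). The cancellation is algebraically exact at this stage; the
   temporal smoothing applied *before* rescaling does not commute with a
   time-varying `s_t`, so end-to-end invariance is exact at σ = 0 and holds
   to high accuracy (identical label maps in practice) at the default σ.
   The rescaled signal is used *only* for classification.
4. **Classification.** Strict comparisons throughout, thresholds
   configurable (defaults: rescaled max > 5, time fractions > 0.5, final >
   0.9·max). Increasing/decreasing time is counted on the signs of the
   discrete derivative over the steps after the trace minimum/maximum;
   zero-derivative steps count only in the denominator ("increasing" is
   read strictly, so flat plateaus do not count as increasing time).
   Argmax/argmin ties resolve to the earliest frame, which makes peak
   alignment deterministic. An extremum on the last frame leaves an empty
   window and a fraction of 0. The necrotic rule is evaluated first: a high
   plateau can satisfy both rules (final below the maximum yet above 90% of
   it) and the plateau reading must win. A vectorized implementation and a
   nested-loop transliteration of the rules are kept side by side; the
   suite requires exact agreement.
5. **Kinetics.** 1000 pixels labelled netotic are sampled uniformly without
   replacement (seeded; fewer available ⇒ all taken, flagged). Their *raw
   smoothed* traces are aligned at their peaking times, normalized by
   `(y − min_prepeak)/(max − min_prepeak)` (no clipping; flat traces dropped
   with a logged count), and summarized by pointwise median/Q1/Q3. Relative
   times covered by fewer than 25% of traces are trimmed so quartiles are
   never computed from a handful of outlier-length traces. Lifetimes are
   first crossings of the 0.5 / 0.2 levels, linearly interpolated between
   the bracketing frames — sub-frame resolution without model assumptions.
   Censoring (level never reached) is reported, never imputed. The unit of
   output is one half-life per field of view: the 50%-lifetime of the
   normalized median curve.
6. **Census and net span.** Initial cells: Otsu components of DAPI frame 0
   with area in [1000, 4000] px (inclusive gates); necrotic cells: necrotic-
   label components in [5000, 10000] px; netotic = initial − necrotic,
   floored at 0 with a warning (noise can invert the difference), under the
   simplifying assumption that every initial cell resolves to one of the
   two fates. Net span = total netotic coverage / netotic count, flagged as
   an underestimate because overlapping NETs are not apportioned.
   Connectivity defaults to 8 (4 available). DAPI thresholding uses Otsu
   for consistency with the Sytox pipeline.
7. **Endpoint NET area.** For a single frame (typically minute 200): Otsu
   mask, connected components, per-component areas. Scale-invariant by Otsu
   covariance.

## Synthetic data: what it emulates, what it does not

`synthetic.random_scene`/`generate_video` render seeded fields with known
ground truth. Defaults are fixed once and document the emulated conditions:

| parameter | default | rationale |
|---|---|---|
| frame interval | 15 min | acquisition cadence of the assay |
| frames | 61 (15 h) | long enough to observe a 12 h half-life post-peak |
| background level / noise | 100 / 5 (sd) | 5% additive Gaussian noise, clipped at 0 — typical wide-field background texture |
| netotic peak | 7–9× background | keeps clear margin over the >5 gate at default noise |
| onset | U(45, 120) min | desynchronized NETosis, early enough to leave a full decay window |
| rise | 30 min (2 frames) | fast dye influx at lysis |
| nucleus footprints | 1500–3500 px disks | inside the 1000–4000 px census gate with rasterization margin |
| NET footprints | 2000–4500 px disks | NETs exceed the nucleus; static (no growth) |
| necrotic footprints | 5500–9500 px disks | inside the 5000–10000 px gate |

Netotic pixels decay exponentially toward background with the configured
half-life after their peak. Necrotic pixels rise to 90% of their amplitude
and then creep linearly to 100% by the final frame: the plateau stays above
90% of the maximum *and* remains strictly increasing in the noiseless
limit, which keeps the "time increasing" criterion decidable under noise —
slowly lysing cells keep accumulating dye, so a gentle monotone plateau is
also the biologically sensible shape. Quiescent cells (DAPI only) default
to zero per scene because the counting identity assumes all initial cells
resolve to a lytic fate.

Not emulated: optics (PSF, shot noise), cell motility, NET growth and
overlap, fungal structures. Passing tests therefore demonstrate that the
*algorithm* recovers known kinetics and censuses under realistic noise and
drift — not that the assay's biological variability is captured.

## Numerical choices

* Otsu via `skimage.filters.threshold_otsu` everywhere a threshold is
  needed; components via `skimage.measure.label`.
* The mean background curve is floored at `1e-6 × max(video)` against
  division blow-ups on pathological inputs.
* Level crossings: first bracketing frame pair after the peak, linear
  interpolation; verified against a dense-grid scan of the same
  interpolant to <0.1 min.
* Problem sizes in the validation suite (256–640 px fields, 41–61 frames,
  ≤20 cells) are chosen so the full synthetic study — 25 half-life
  recovery fields plus census, quality and determinism checks — runs on a
  single CPU in a few minutes while keeping every footprint inside the
  census gates; field size does not enter the kinetic conditions.
* Half-life recovery carries a small positive bias (≈ +5 to +12 min across
  90–720 min truths): Gaussian smoothing blunts the peak, and peak-aligned
  normalization by the smoothed maximum shifts the 0.5-crossing slightly
  late. The bias stays inside one frame interval, the resolution of the
  assay.

## Known limitations

* Exact end-to-end drift invariance holds at σ = 0; at σ > 0 smoothing and
  time-varying drift do not commute, so invariance of the label map, while
  observed across the shipped conditions, is not a mathematical guarantee
  for adversarial drift profiles.
* The netotic count is derived, not observed; it inherits both census
  gates' errors.
* Net span underestimates per-cell NET extent when NETs overlap (no
  apportioning is attempted).
* Group-level statistics across conditions (rank tests, plotting beyond
  diagnostics) are out of scope; the per-field half-life is the terminal
  output.
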