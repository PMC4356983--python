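# pmtraffic

Quantification of plasma-membrane protein traffic from high-content
fluorescence microscopy screens.

The pipeline takes multiwell plates of three-channel fields — a DNA stain
(nuclei), a total-reporter channel, and a surface-label immunostain — and
produces per-cell, per-image and per-condition readouts of *traffic
efficiency* (integrated surface / integrated total fluorescence per cell),
with deviation-score-based hit calling for siRNA or compound screens.

Stages:

1. **synthetic_plate** — a plate simulator with per-cell ground truth:
   lognormal expression heterogeneity, condition-specific true
   surface/total ratios, smooth illumination gradients plus background,
   12-bit detector saturation, apoptotic-like small cells, defocused
   fields and control wells.
2. **image_correction** — per-channel illumination correction functions
   (pixel-wise median across the plate, large-kernel median smoothing),
   *subtracted* from each field; residual background in cell-free areas
   checks subtraction accuracy.
3. **segmentation** — Otsu + distance-transform watershed nuclei, seeded
   region growing for cell bodies, exact per-cell intensity integration.
4. **quality_control** — cell-level flags (low expression, saturated
   pixels, abnormal morphology), image-level exclusion (plate-adaptive
   variance-of-Laplacian focus gate, residual background, minimum cell
   count), and plate-level transfection QC (reject when the expected
   phenotype is missing in more than 75% of control images).
5. **screen_scoring** — per-image median readouts, per-condition mean ±
   SEM, deviation score `(mean_test − mean_neg) / (2 × SEM_neg)`,
   enhancer/inhibitor calls above +1 / below −1, and two-tailed Student's
   t-tests versus the negative control, for all three readouts
   (traffic efficiency, total, surface).
6. **pipeline_io** — filename schema, plate layouts, orchestration,
   result bundle (CSV tables + plain-text report + manifest) and the CLI.

## CLI

```sh
# simulate a demo plate (images, ground truth, layout, phenotype flags)
pmtraffic simulate --out demo_plate/ --seed 1

# full analysis: correction -> segmentation -> QC -> scoring
pmtraffic run --images demo_plate/ --layout demo_plate/layout.csv --out results/

# inspect
pmtraffic report --results results/
```

Other subcommands: `correct` (estimate illumination profiles only),
`segment` (write the per-cell table only), `score` (re-score a per-image
summary CSV). `--config` accepts a YAML file overriding any
`PipelineConfig` default (see `src/pmtraffic/config.py`); simulator
parameters are a separate YAML (`SimulationConfig`).

Input images are per-channel single-plane TIFFs (12-bit data in 16-bit
containers) named by a configurable template, default
`{well}_f{field:02d}_ch{channel}.tif` with channels 1/2/3 mapped to
nuclei/total/surface. The layout CSV has columns
`well,condition,class,control_role` and must contain a negative control.
Plate-level transfection QC consumes per-image boolean phenotype flags
(`phenotype_flags.csv`: `well,field,phenotype`) — ground truth in
simulation, an annotation file on real data.

## Notes

- Determinism: simulation is fully seeded; analysis is deterministic given
  inputs and configuration (a rerun produces bit-identical CSVs).
- The correction is subtractive (not division flat-fielding); corrected
  intensities clamp at zero.
- The classifier thresholds are strict: a score of exactly ±1 is neutral,
  and a plate with a control-failure fraction of exactly 0.75 is accepted.
- p-values are raw (no multiple-testing correction); treat small ones
  across many conditions accordingly.
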