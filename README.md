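# habscape

Multiscale habitat-suitability modelling on raster landscapes, runnable end
to end on synthetic data with known ground truth. The pipeline combines:

- **Climate suitability models** — lasso-penalized presence–background
  logistic regression (maxnet-style linear/quadratic/hinge features) with a
  regularization-multiplier sweep (0.5–3.0 by 0.5) scored by AIC, seasonal
  (winter Nov–Feb / summer May–Sep, month-matched predictors) and
  historical-niche variants, checkerboard spatial cross-validation,
  projection onto a pseudo-GCM future ensemble (mean + binary-sum consensus),
  and a MOP extrapolation/similarity surface.
- **Three independent habitat models** — a four-learner ensemble RSF
  (penalized logistic, random forest, CART, logistic GLM; equal-weight mean),
  a step-selection function (per-individual gamma/von Mises random steps,
  K = 15 controls per observed step, Newton conditional-logistic fit), and an
  expert habitat suitability index (piecewise-linear response curves combined
  multiplicatively with a land-cover sum, urban/agriculture zeroed).
- **Consensus mapping** — occurrence-percentile thresholds (exact type-1
  quantile retention guarantee), clipping to climate suitability, 0–3
  consensus summation, conflict-class masking, and area accounting.
- **Evaluation** — Mann–Whitney AUC and the continuous Boyce index, with
  cross-source pairing (models are never scored on their own training data).
- **Synthetic data** — exponential-covariance Gaussian random fields
  (circulant embedding), seasonal climate cycles, categorical land cover,
  road networks, occurrences sampled from a known logistic suitability
  surface, movement tracks driven by a known step-selection rule, and
  perturbed pseudo-future climate stacks — every generator a pure function of
  (config, seed).

## CLI

```sh
# generate a synthetic landscape + occurrence/track CSVs
habscape simulate --seed 3 --grid 100x100x500 --out scratch/sim

# filter + season-split occurrence records
habscape prep --occurrences scratch/sim/occurrences.csv --out scratch/prep

# full pipeline on synthetic inputs (deterministic for a fixed seed)
habscape run --simulate --seed 7 --grid 100x100x500 --n-gcm 3 --out scratch/run
```

`run` writes every stage artifact (suitability surfaces, thresholds, MOP,
consensus maps, area tables, evaluation CSV) plus `pipeline.log` and
`manifest.json`. Reruns with the same config and seed are bit-identical.
Other subcommands (`fit-climate`, `project`, `threshold`, `consensus`)
operate on TIFF/CSV files for piecemeal use.

## Layout

| module | contents |
| --- | --- |
| `habscape.grids` | Grid/Raster/RasterStack, resampling, slope, TPI, distance, focal density, TIFF I/O |
| `habscape.synth` | landscapes, occurrences, movement tracks, pseudo-future climate |
| `habscape.occurrences` | record filters, season split, thinning, background sampling, covariate extraction |
| `habscape.climate` | penalized presence–background model, sweep, checkerboard CV, projection, MOP |
| `habscape.rsf` | four-learner ensemble fit/predict |
| `habscape.ssf` | step construction, random steps, conditional-logistic fit, suitability surface |
| `habscape.expert` | response curves and the multiplicative expert index |
| `habscape.evaluation` | AUC, continuous Boyce, cross-source evaluation |
| `habscape.consensus` | thresholds, clipping, consensus sum, masking, areas |
| `habscape.pipeline` / `habscape.cli` | orchestration and the `habscape` command |
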