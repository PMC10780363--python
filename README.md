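# soyspec

Multi-layer leaf nitrogen concentration (LNC) estimation from canopy
hyperspectral reflectance, built as a fully testable pipeline on a
synthetic field experiment:

1. **synthetic field experiment** (`soyspec.simulate`) — a 2-year x
   4-nitrogen-rate x 2-inoculation x 3-replicate factorial (48 samples)
   with three vertically ordered leaf layers (RL < LL < CL) and a
   parametric reflectance model (chlorophyll wells, green peak, logistic
   red edge, NIR plateau, SWIR water dip) driven by the canopy-layer LNC;
2. **preprocessing** (`soyspec.preprocess`) — Savitzky–Golay smoothing
   (9-point window, order 4, mirror edges) and forward first-derivative
   spectra on the 350–1830 nm / 1 nm grid;
3. **spectral parameters** (`soyspec.parameters`) — 10 empirical indices,
   10 three-edge ("trilateral") derivative parameters, and 10 dual-band
   formulas (RI, DI, SAVI, NDVI, TVI, mSR, mNDI, PI, SI, VI6);
4. **two-band optimization** (`soyspec.bandsearch`) — exhaustive
   wavelength-pair Pearson-correlation surfaces per formula with argmax
   selection (ties to the smallest i, then j);
5. **screening** (`soyspec.screening`) — per-class significance
   filtering (p < 0.05 against each layer's LNC) into four input
   combinations (empirical / dual-band / trilateral / mixed);
6. **estimation** (`soyspec.estimation`) — a 3-layer x 4-combination x
   3-model grid (PLSR with 10-fold-CV latent-variable selection, a
   600-tree random forest, and a 15-unit tanh network trained by
   Levenberg–Marquardt) evaluated by R², RMSE and MRE on a shared
   2/3 : 1/3 modeling/validation split.

## CLI

```sh
soyspec simulate --seed 1 --out data/            # spectra.csv + lnc.csv
soyspec preprocess --in data/spectra.csv --out data/smoothed.csv
soyspec search --spectra data/smoothed.csv --lnc data/lnc.csv \
    --layer CL --stride 5 --out search/          # best pairs + surfaces
soyspec indices --spectra data/smoothed.csv --pairs pairs.json --out params.csv
soyspec screen --params params.csv --lnc data/lnc.csv --out combos.json
soyspec fit --params params.csv --lnc data/lnc.csv --combos combos.json \
    --seed 1 --out fit/
soyspec run-all --seed 1 --stride 5 --out run/   # everything + manifest
```

`run-all` writes `metrics.csv` (layer, combination, model, split, r2,
rmse, mre_percent, n, seed), `predictions.csv`, per-formula best pairs,
the screened combinations, and a `manifest.json` with the config hash
and a content hash per output file; reruns with the same seed are
byte-identical. Pass `--figures` to also render correlation heatmaps
and observed-vs-predicted scatter plots.

The default search stride is 5 nm (297 bands, ~88k ordered pairs per
formula); set `--stride 1` for the full 1481-band search.

## Notes

- R² defaults to the ratio form `sum((yhat-ybar)^2)/sum((y-ybar)^2)`;
  `r2_form="conventional"` selects `1 - SSE/SST`.
- Undefined parameter values (log/ratio singularities) are NaN
  sentinels, counted and excluded pairwise from correlations, never
  zero-filled.
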