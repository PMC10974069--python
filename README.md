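# leafmetal

Indirect estimation of soil heavy-metal content (Cd, As) from rice-leaf
reflectance spectra. The package implements the full chemometric workflow:

1. **`leafmetal.cohort`** — synthetic cohort generator producing paired
   (leaf spectra, soil chemistry) data: truncated log-normal Cd/As marginals
   coupled through a numerically calibrated Gaussian copula, and
   vegetation-shaped reflectance curves (chlorophyll wells at 450/670 nm,
   green peak, red edge, NIR plateau) whose absorption depth shrinks with a
   metal-stress index, plus affine scatter and channel noise.
2. **`leafmetal.preprocessing`** — band trimming (≥ 380 nm), Savitzky–Golay
   smoothing, and the transforms R, FD, SD, AT, AFD, ASD, MSC, SNV.
3. **`leafmetal.plsr`** — single-response NIPALS partial least squares with
   autoscaling, pooled cross-validation over component counts (leave-one-out
   by default; a numba-accelerated kernel with a pure-numpy fallback), and
   JSON model serialization.
4. **`leafmetal.ga`** — genetic-algorithm wavelength selection: binary band
   masks, tournament selection, uniform crossover, bit-flip mutation,
   elitism; fitness is the cross-validated RMSE of PLSR on the masked bands;
   repeated runs with derived sub-seeds and best-of-repeats aggregation.
5. **`leafmetal.evaluation`** — ordered one-in-four modeling/validation
   split, RMSE / R² / RPD metrics, the five-level RPD interpretation
   (poor < 1.5 … excellent > 3.0), and paired GA-PLSR vs full-band PLSR
   comparison reports.
6. **`leafmetal.pipeline` / `leafmetal.cli`** — end-to-end orchestration
   with one root seed, run manifests, and CSV/JSON reports.

## CLI

```bash
leafmetal generate --seed 1 --spectra-out spectra.csv --soil-out soil.csv
leafmetal preprocess --transform AFD --spectra spectra.csv --out afd.csv
leafmetal select --metal cd --transform AFD --spectra spectra.csv --soil soil.csv --seed 1
leafmetal fit --metal cd --transform AFD --spectra spectra.csv --soil soil.csv --mask mask.json
leafmetal evaluate --metal cd --transform AFD --spectra spectra.csv --soil soil.csv --model model.json
leafmetal run-all --seed 1 --out runs/demo            # full 8×2 sweep (~4 min)
```

`run-all` writes `reports.csv` (long form), `comparison.csv` (GA vs
full-band with percent changes), `comparison.json`, per-channel GA
`selection_frequency.csv`, the generated cohort CSVs, and a `manifest.json`
that reproduces the run exactly.

Spectra CSVs are wide format: a `site_id` column followed by one column per
wavelength channel (nm); soil CSVs have columns
`site_id,ph,cd_mg_kg,as_mg_kg`.

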