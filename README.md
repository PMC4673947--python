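# ftirdose

Predicting the effective dose of a cytotoxic agent from FTIR spectra of
exposed cells.

Standard cytotoxicity assays (MTT, clonogenic survival) report *whether*
cells die, not *which molecular sites* a toxicant hits or what exposure
a given biochemical state implies. Mid-infrared spectroscopy sees those
sites directly: platinum drugs such as cisplatin shift DNA base
vibrations (guanine 1725 → 1713 cm⁻¹, thymine 1665 → 1657 cm⁻¹) and the
protein amide β-sheet band (1639 → 1624 cm⁻¹), while phosphate bands
stay put. `ftirdose` implements the full analysis chain that turns such
spectra into a dose predictor, for chemometricians and toxicologists who
want a tested, reproducible reference implementation:

- **Biochemical index spectra (BIS)** — each exposed replicate minus the
  mean control spectrum, the difference fingerprint of exposure;
- **PLS1 regression by NIPALS** (written from scratch, oracle-tested):
  X = BIS intensities, y = concentration; latent variables chosen by
  cross-validation; b = W(PᵀW)⁻¹q;
- **evaluation protocol** — 20 stratified random splits of the 56 BIS
  rows into 40 train / 16 test, scored with RMSE and
  R² = 1 − SS_res/SS_tot over five wavenumber windows;
- **Hill dose–response** — mortality% = 100·cʰ/(LC50ʰ + cʰ) fit to
  clonogenic assay tables, LC50 estimation;
- **synthetic-data generator** — dose-structured Gaussian-band spectra
  with logistic band shifts, difference-spectrum markers at
  +1648/−1490 cm⁻¹, replicate noise and baseline drift, emulating a
  9-concentration × 7-replicate cisplatin/HepG2 design so the whole
  chain runs without any external data.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import numpy as np
from ftirdose import (GeneratorConfig, generate_design, preprocess_collection,
                      compute_bis, stratified_split, fit_pls, predict,
                      r_squared, rmse)

collection = preprocess_collection(generate_design(GeneratorConfig(seed=1)))
bis = compute_bis(collection)           # 56 rows x 2001 wavenumbers
split = stratified_split(bis, seed=1)   # 40 train / 16 test, 5/2 per dose
model = fit_pls(bis.X[split.train_indices], bis.y[split.train_indices], n_lv=10)
pred = predict(model, bis.X[split.test_indices])
obs = bis.y[split.test_indices]
print(f"test R^2 = {r_squared(obs, pred):.3f}, RMSE = {rmse(obs, pred):.3f} ug/mL")
```

prints

```
test R^2 = 0.994, RMSE = 0.100 ug/mL
```

i.e. a 10-latent-variable PLS model predicts held-out cisplatin
concentrations to about ±0.1 µg/mL over the 0.125–4 µg/mL design.

The numbered drivers under `analysis/` run the complete study and write
their tables to `results/`:

```sh
python analysis/01_simulate_spectra.py --seed 1   # 63 spectra + clonogenic counts
python analysis/02_preprocess_spectra.py          # ALS baseline + 0-1 normalization
python analysis/03_bis_band_shifts.py             # BIS matrix, band/marker trajectories
python analysis/04_pls_window_evaluation.py --seed 1
python analysis/05_dose_response_fit.py           # Hill fit, LC50
```

Step 04 prints, per window, the mean ± sd of test-set R² over the 20
splits (full 1000–3000 cm⁻¹ window ≈ 0.99; the construction-silent
2000–2500 cm⁻¹ window ≈ 0; shuffled-label control < 0), and step 05
prints `LC50 = 0.304 ug/mL ... Hill slope = 1.52` for the bundled HepG2
reference assay. The same stages are available as a CLI
(`ftirdose simulate|preprocess|bis|train|predict|evaluate|dose-response|run`);
`ftirdose run --seed 1 --output-dir results` executes everything and
writes a manifest that reproduces the run.

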