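# emsckit

Extended Multiplicative Signal Correction (EMSC) for infrared and other
vibrational spectra: model-based separation of chemical signal from physical
artifacts, with constituent spectra, per-channel weighting, collinearity
diagnostics, synthetic data generators and end-to-end calibration and
segmentation pipelines.

## The science

Measured ("apparent") absorbance spectra mix the chemistry of the sample with
physical effects: multiplicative path-length/scattering scaling, additive
baseline drifts, and contributions from constituents that are not of
interest. EMSC models each apparent spectrum `Z` as

```
Z = b·Zref + Σₖ pₖ·Tₖ + Σⱼ fⱼ·Zanaⱼ + Σⱼ gⱼ·Zintⱼ + ε
```

where `Zref` is an artifact-free reference spectrum (typically the dataset
mean), `Tₖ` are polynomial baseline terms in a wavenumber coordinate centered
to [-1, 1], `Zana` are *analyte* spectra whose contribution should be kept,
and `Zint` are *interferent* spectra whose contribution should be removed.
The parameters of each spectrum are estimated by least squares, and the
corrected spectrum inverts the physical terms:

```
Zcorr = (Z − Σₖ pₖ·Tₖ − Σⱼ gⱼ·Zintⱼ) / b  =  Zref + Σⱼ (fⱼ/b)·Zanaⱼ + ε/b
```

Baselines and interferents are subtracted; analytes and the residual are
retained and rescaled. The ratio `f/b` ("relative content") is proportional
to the analyte concentration per unit sample and is the quantity to use in
downstream calibration.

Key facts the implementation guarantees and the test suite verifies:

* **Exact inversion.** On noise-free data generated from the model itself,
  parameters are recovered to machine precision and the corrected spectra
  equal `Zref + (f/b)·Zana`.
* **Orthogonal-analyte invariance.** Adding an analyte orthogonal to the
  span of the existing design does not change the corrected spectra at all —
  its parameter simply reads off the projection of the residual. Adding an
  orthogonal *interferent* shifts each corrected spectrum by exactly
  `−(g/b)·Zint`.
* **Weighting.** A non-negative per-channel weight vector steers the fit;
  both the design columns and the measured spectrum are multiplied by it
  (a `design_only` mode is available as a configuration switch). Channels
  with zero weight are exactly inert: arbitrary garbage there cannot move
  any parameter. Residuals are always reported in the unweighted metric.
* **Collinearity diagnostics.** Constituent spectra that are nearly linear
  combinations of the reference and the other design columns make the
  parameters unstable — the classic failure mode is using one group's mean
  as reference and another group's mean as analyte, which collapses `b`
  (even to negative values). `collinearity_diagnostics` reports pairwise
  correlations and the condition number of the normalized design and flags
  `|corr| > 0.95` or `cond > 1e6`.
* **Analyte estimation from residuals.** When no analyte spectrum is known
  a priori, the leading PCA loading of the EMSC residuals recovers the
  missing constituent direction; PCA on residuals and on corrected spectra
  give the same loading up to sign.

## Worked example

Correct a two-group protein-like dataset with random baseline disturbances,
then calibrate a solute concentration on a solvent/solute mixture series:

```python
import numpy as np
from emsckit import (EMSCModelSpec, MixtureScenario, TwoGroupScenario,
                     fit_correct, make_mixture_series, make_two_group,
                     run_case2)

# --- correction ---------------------------------------------------------
data, labels, _ = make_two_group(TwoGroupScenario(seed=0, add_baselines=True))
spec = EMSCModelSpec(reference=data.mean_spectrum(), polynomial_order=2)
result = fit_correct(spec, data)
p = result.params[0]
print(f"first spectrum: b = {p.b:.4f}, baseline = "
      f"[{p.poly[0]:.4f}, {p.poly[1]:.4f}, {p.poly[2]:.4f}]")

# --- calibration --------------------------------------------------------
mix, conc, truth = make_mixture_series(MixtureScenario(seed=0))
res = run_case2(mix, conc, "estimated_analyte")
cal = res.calibration
print(f"reference spectrum: {res.reference_id}")
print(f"slope={cal.slope:.4f} intercept={cal.intercept:.4f} "
      f"RMSE={cal.rmse:.3f} g/L  R2={cal.r2:.5f}")
r = np.corrcoef(res.analyte.values, truth["solute_spectrum"])[0, 1]
print(f"loading vs true solute correlation: {r:.4f}")
```

Output:

```
first spectrum: b = 1.0206, baseline = [0.0068, -0.0481, 0.0017]
reference spectrum: mix_03
slope=188.5335 intercept=1.9807 RMSE=0.109 g/L  R2=0.99998
loading vs true solute correlation: 0.9996
```

The calibration pipeline picked the most dilute mixture as its solvent-like
reference, estimated the solute spectrum from residual PCA with the
chemically active 950–1200 cm⁻¹ region down-weighted to zero, and regressed
`f/b` against the known concentrations — recovering them with an R² of
0.99998 and a loading that correlates with the true solute spectrum at
r = 0.9996.

## Command-line interface

The `emsc` command exposes the same functionality:

```
emsc simulate two-group --seed 0 --baselines --out tg
emsc correct --input tg_spectra.csv --poly 2 \
     --out-spectra corrected.csv --out-params params.csv
emsc estimate-analyte --input tg_spectra.csv --out loading.csv
emsc diagnose --input-model model_spectra.csv --poly 2
emsc simulate mixture --seed 0 --out mix
emsc case2 --input mix_spectra.csv --response mix_concentrations.csv
emsc simulate image --seed 0 --out img
emsc case3 --image img_image.csv --out-mask mask.txt
```

Exit codes: 0 success, 2 validation error (bad files/arguments/degenerate
data), 3 ill-posed least-squares model without `--force`.

Spectra files are CSV/TSV matrices: first column `wavenumber`, one column
per spectrum, 12 significant digits. Images use a long-format table with
columns `x, y, wavenumber, absorbance`.

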