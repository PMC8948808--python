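# Methods note

This note records the model implemented by `emsckit`, the design of the
synthetic data generators, the numerical choices, and known limitations.
Every empirical statement here is computed by the test suite
(`tests/`) or by `scripts/acceptance.py`.

## Model

Each apparent spectrum `Z` on a common wavenumber axis is modeled as

```
Z = b·Zref + Σₖ₌₀..P pₖ·Tₖ + Σⱼ fⱼ·Zanaⱼ + Σⱼ gⱼ·Zintⱼ + ε
```

* `Zref` — reference spectrum (any non-zero vector; typically the dataset
  mean). The constant term `a` is identified with `p₀` (the degree-0
  polynomial coefficient).
* `Tₖ` — polynomial baselines of degree k in the centered coordinate
  `t = (ν − ν_mid) / ((ν_max − ν_min)/2) ∈ [−1, 1]`. The order is capped at
  7 and a warning is emitted above 2, because high orders start absorbing
  chemical band shapes.
* `Zanaⱼ` / `Zintⱼ` — analyte and interferent constituent spectra. In the
  design they are rescaled to unit Euclidean norm; the applied scale factors
  are recorded (`DesignMatrix.constituent_scales`), so reported `f`/`g` are
  per unit-norm constituent.

Parameters are estimated per spectrum by linear least squares
(`numpy.linalg.lstsq` on the stacked design). The corrected spectrum is

```
Zcorr = (Z − Σₖ pₖ·Tₖ − Σⱼ gⱼ·Zintⱼ) / b
```

keeping the analyte contributions and the rescaled residual. Relative
contents `f/b` and `g/b` are the concentration-proportional quantities.

### Weighting

A non-negative weight vector `w` multiplies both the design columns and the
measured spectrum before solving (default, `weight_mode="both"`); a
`design_only` mode that weights only the model spectra is available as a
configuration switch. For binary weights the two modes coincide with
ordinary least squares restricted to the kept channels, which the tests
verify against an explicit sub-region solve. Zero-weight channels are
exactly inert. Weights are scale-invariant (`c·w` gives the same fit).
Residuals are always computed in the unweighted metric so that downstream
residual PCA is not distorted by the weighting.

### Degeneracies

* `b` within `1e-8 · max|Zref|` of zero: correction is undefined; the
  affected spectra are flagged (`b_near_zero`) and emitted as missing rows
  unless the caller forces an error.
* Rank-deficient designs raise `IllPosedError` (SVD rank check with
  tolerance `s₀ · max(shape) · eps`) unless `force=True`, which returns the
  minimum-norm solution.
* `collinearity_diagnostics` reports the pairwise cosine similarities of
  the design columns and the condition number of the column-normalized
  design (via SVD), flagging `|corr| > 0.95` or `cond > 1e6`.

### Constituent estimation

When no analyte spectrum is known, the leading principal-component loading
of the mean-centered EMSC residual matrix estimates the missing constituent
direction (SVD; sign fixed so the largest-magnitude element is positive).
Because the residuals are orthogonal to the design span, the loading is a
valid design-orthogonal analyte: appending it leaves the corrected spectra
unchanged, and its fitted `f` equals the projection of each residual onto
the loading (the uncentered PCA score). PCA on the corrected spectra gives
the same leading loading up to sign (cosine ≥ 0.999 on the mixture data,
verified in the acceptance suite); `scikit-learn` is used in the tests only
as an independent cross-check of the SVD extraction.

## Synthetic scenarios

All generators are deterministic per seed and return the ground truth used
by the tests. Their default parameters are fixed study conditions, not
tuning knobs.

### Two-group protein-like set

Spectra are sums of Lorentzian bands
`L(ν) = Σ h·γ²/((ν−ν0)² + γ²)` (γ = half width at half maximum) on a
500–4000 cm⁻¹ axis at 2 cm⁻¹ spacing. A fixed band table (broad
3300 cm⁻¹ O-H/N-H envelope, C-H stretches, CH bends, amide III,
carbohydrate C-O bands) is shared by all spectra; only the amide I
(1653 cm⁻¹) and amide II (1545 cm⁻¹) heights vary: group 1 scales them
uniformly in [0.85, 1.0], group 2 in [0.40, 0.55], 20 spectra per group.
The broad envelope dominates the spectrum norm, so the two group means are
strongly dependent (|corr| > 0.99) even though the amide bands differ by a
factor ≈ 2 — the precondition for the scaling-collapse pitfall, where using
group 1's mean as reference and group 2's mean as analyte drives `b`
negative for group-2 spectra. Optional constant/linear/quadratic baselines
with coefficients uniform in [−0.1, 0.1] emulate physical disturbances;
Gaussian noise σ = 1e-3.

An order-2 EMSC on the baseline-disturbed set leaves a systematic
between-group offset at the high-wavenumber edge (gap > 5× its standard
error), because the amide tails leak into the baseline terms differently
per group. Supplying the *clean* group-mean difference spectrum as analyte
removes it (gap < 2× SE). The difference spectrum must come from
disturbance-free data: the random baselines do not average out over 20
spectra, so a difference of disturbed group means carries baseline
contamination of the same order as the artifact itself.

### Solvent/solute mixture series

Water-like solvent (broad 3350 cm⁻¹ O-H stretch, 1640 cm⁻¹ bend, flat
through 950–1250 cm⁻¹) plus a glucose-like solute fingerprint with a
1080 cm⁻¹ marker, on an 800–3700 cm⁻¹ axis. Each of 40 samples is
`thickness · (solvent + c · 1e-3 · solute) + offset + noise` with
concentration `c` uniform in [0.55, 80] g/L, thickness in [0.9, 1.1],
offset in [−0.005, 0.005], σ = 5e-4. The axis deliberately covers the
full O-H envelope: truncating it mid-band leaves a ramp that the least
squares projection can absorb into the reference coefficient, corrupting
the residual loading.

Two calibration routes are implemented: `known_analyte` (order-0 EMSC with
the true solvent reference and solute analyte) and `estimated_analyte`
(reference picked as the most solvent-like spectrum by the
1080-vs-1200 cm⁻¹ marker contrast; first-pass order-0 fit with zero weights
on 950–1200 cm⁻¹; analyte = first residual loading; unweighted refit).
Both reach R² ≥ 0.99 against the true concentrations and the estimated
loading correlates with the true solute spectrum at |r| ≥ 0.99.

### Two-class hyperspectral image

A 64×64 image on 900–1800 cm⁻¹ at 4 cm⁻¹ spacing. Class B occupies a
contiguous wavy region (`x > w/2 + 0.15·w·sin(2πy/h)`) and adds a
collagen-like contrast (amide III gains, amide I deficit) at amplitude
0.05 to the shared protein template. The raw contrast is orthogonalized
against the template and the constant/linear baselines before use: a
chemical difference spectrum is by definition the part of the class
difference that scaling and baseline terms cannot absorb, and only that
part is recoverable from model residuals. Per-pixel thickness in
[0.8, 1.2], baselines in [−0.05, 0.05], σ = 2e-3.

Segmentation fits an order-1 EMSC with the image mean as reference,
estimates the first residual loading, refits with it as analyte, and
thresholds `f` at 0. Because the loading is design-orthogonal, `f` is
identically the residual projection score, so parameter-based and
PCA-score-based segmentation agree exactly; agreement with the ground-truth
mask is ≥ 99 % (label-swap invariant).

## Numerical choices

* Batch least squares through `numpy.linalg.lstsq`; acceptance verifies
  equality with an independent `numpy.linalg.pinv` oracle to 1e-8 over 200
  randomized designs (observed ≈ 4e-15).
* Condition numbers and PCA loadings via `numpy.linalg.svd`.
* File I/O: CSV matrices written with 12 significant digits (`%.12g`),
  which round-trips float64 spectra to ~1e-12 relative; images use a
  pandas long-format table.
* Child seeds are derived with `numpy.random.SeedSequence` and reduced
  below 2³¹.

## Limitations

* Parameters are estimated independently per spectrum; no shared or
  regularized estimation across a dataset.
* No mixture-closure constraint (Σ concentrations = 1) is imposed on
  constituent parameters.
* Polynomial baselines only; no scattering-theory (e.g. Mie-type)
  extensions.
* The replicate-based weight-estimation workflow is not implemented;
  weights must be supplied by the user.
* Calibration metrics (R², RMSE) are apparent (training) values, not
  cross-validated.
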