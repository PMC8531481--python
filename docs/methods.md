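# Methods

This note documents the models and numerical conventions of `sportfuse`:
what each stage computes, the defaults and why, what the synthetic
generator does and does not emulate, and the design choices made where the
design was genuinely open.

## Synthetic FT-IR generator

Each spectrum on the ascending wavenumber grid v (default 400–4000 cm⁻¹,
4 cm⁻¹ step) is

    x(v) = g · Σ_b A_b · exp(−(v − c_b)² / 2σ_b²) + o + κ·u(v)² + ε(v)

with band centers c_b fixed at the eight dominant mid-IR absorptions of
dried gentian root powder (3400, 2928, 2857, 1615, 1427, 1375, 1260,
1057 cm⁻¹), widths σ_b of 30–180 cm⁻¹ (broad O–H/C–O envelopes, narrow
CH bends), and base amplitudes A_b on an absorbance scale of ~0.3–0.9.
Per-sample artifacts: multiplicative gain g = exp(N(0, 0.15)), additive
offset o ~ N(0, 0.05), a quadratic baseline with curvature
κ ~ N(0, 0.03) on the normalized coordinate u, and white noise
ε ~ N(0, 0.005). Gain and offset are exactly the affine artifact model
MSC/SNV assume, so in the noise-free limit the corrections invert them
exactly — this is what lets the preprocessing tests assert recovery of
ground truth rather than plausibility.

Class structure: each of the 5 origin classes perturbs the band
amplitudes by `class_effect_size` times a fixed per-class pattern in
[−1, 1] drawn once from a seed-derived stream; with effect size 0 the
classes are exchangeable and classification accuracy is at chance.
Analyte content (total secoiridoids, mg/g) is lognormal, parameterized by
its mean (10 mg/g) and coefficient of variation (0.252) — lognormal
because content must stay positive while matching a stated CV — and
scales the amplitudes of designated bands (defaults: the 1615 and
1057 cm⁻¹ bands) linearly, giving the regression task a known signal.

Default sample sizes follow the emulated study conditions: 5 classes of
~55 samples (a 273-sample quantitative design; the 2:1 split default of
182/273 matches). The generator does **not** emulate interferometer
physics (apodization, resolution effects), KBr-pellet preparation
variability, water-vapor/CO₂ lines, batch or day effects, or non-affine
scattering (wavelength-dependent gains). Passing tests therefore show the
algorithms are correct under the stated artifact model, not that any
particular accuracy will be achieved on real spectra.

## Scatter corrections

* **SNV** — each row standardized to mean 0, sample SD 1 (denominator
  n−1). Stateless; a constant row is an error naming the sample.
* **MSC** — each row x regressed on a reference spectrum by ordinary
  least squares, x ≈ a·ref + b, then corrected as (x − b)/a. Reference:
  the training-set mean spectrum, frozen for test rows. |a| < 1e−12 is a
  degenerate-spectrum error.
* **VSN** — weighted MSC. Per-variable weights in [0, 1] are estimated by
  deterministic iterative reweighting: starting uniform, each of
  `vsn_iterations` (default 5) passes fits every spectrum affinely under
  the current weights, pools absolute residuals per variable (median over
  samples), rescales by their median, and maps through
  w = exp(−(r/bandwidth)²) with bandwidth 1.0. Variables dominated by
  chemical signal acquire large pooled residuals and are down-weighted, so
  the affine fit is driven by scatter-dominated regions. This is an
  intent-preserving approximation of the published variable-sorting
  scheme, not a line-by-line reimplementation; with 0 iterations the
  weights stay uniform and VSN reduces exactly to MSC (tested). Weights
  are estimated on training rows and frozen. All weights collapsing below
  1e−8 raises an error suggesting a larger bandwidth.
* **SD** — Savitzky-Golay second derivative, window 11 points, polynomial
  order 3 (common FT-IR practice; both configurable), scaled by the grid
  step so units are absorbance·cm². Edges use the filter's one-sided
  polynomial fits (`mode="interp"`), keeping output length equal to input
  length so all blocks share one wavenumber grid; this is recorded in
  provenance.

Any data-dependent state (MSC/VSN reference, VSN weights) is estimated on
training rows only; `PreprocessingBank` packages the fit/apply split.

## Synchronous 2D correlation maps

Dynamic spectra are deviations from the mean spectrum of the perturbation
series (the standard generalized-2DCOS reference choice); the synchronous
intensity is Φ = SᵀS/(m−1), i.e. the sample covariance of dynamic
intensities, with samples playing the role of perturbation steps (an
explicit ordering hook exists but Φ is ordering-invariant). The diagonal
equals the per-variable dynamic variance — asserted against an
independently coded variance in tests. `map_difference` normalizes each
map by its own maximum absolute intensity before differencing, so the
complementarity summary reflects structure rather than scale; it reports
the Frobenius norm and auto-peak (diagonal) discrepancies.

## PLS engine

NIPALS with Y-deflation (PLS2 for one-hot classification, PLS1 for a
content vector). Determinism: the score iteration is initialized from the
residual-response column of maximal variance; convergence is declared when
the normalized weight vector changes by < 1e−9 (max 1000 iterations — a
warning, never silence, otherwise). Components whose weight or score norm
falls below 1e−10 relative to the matrix scale terminate extraction
(rank exhaustion), with a logged warning when fewer components than
requested are extractable. At full rank the coefficients reproduce the
least-squares solution (oracle-tested on random instances).

* **Kennard-Stone split**: seed pair = the two samples at maximal
  Euclidean distance; each pick maximizes the minimal distance to the
  selected set; all ties resolve to the lowest index. Note that maximin
  selection anti-correlates train and test class frequencies, which
  biases *null* classification accuracy below chance — the chance-level
  calibration tests therefore use a class-balanced split.
* **Cross-validation**: deterministic venetian blinds (sample i → fold
  i mod 7). One NIPALS fit per fold at the maximal count yields nested
  predictions for every smaller count. The chosen LV count minimizes
  RMSECV; values within 1e−8 of the minimum (relative to the response RMS)
  are treated as tied and resolve to the smallest count, so noise-free
  plateaus select the true dimension.
* **R² convention**: reported "correlation coefficients" are coefficients
  of determination, 1 − SSE/SST, on calibration (R²c) and prediction
  (R²p) sets — the convention of the chemometrics software the emulated
  workflow standardizes on.
* **Permutation test**: the response is permuted `n_iter` times (default
  200) and the full pipeline, including LV selection, is refit each time;
  the statistic is cross-validated accuracy (classification) or Q²
  (regression) — a single scalar with a clean one-sided p-value
  p = (1 + #{null ≥ observed})/(n_valid + 1), rather than an
  intercept-plot criterion. Failures inside a permutation are warned and
  excluded, never silent.
* **Model comparison**: percent change 100·(b − a)/a per metric, rounded
  to one decimal for display, with the baseline always explicit in the
  comparison label.

## SPORT

Blocks (differently preprocessed copies, default order
MSC → SNV → VSN → SD; configurable, and the fitted result is largely
order-insensitive for the classification outcome) are fit sequentially:
block i is orthogonalized against the accumulated training scores by
least-squares projection (the projection loadings are stored and reused
at prediction time), then a PLS model on the orthogonalized block fits
the current response residuals. The final response fit regresses the
centered response on the fused score matrix [T₁ | … | T_B]; since block
scores are mutually orthogonal this equals the sum of sequential fits,
while also absorbing any residual non-orthogonality.

LV selection is exhaustive over {0…max_lv}^B (default max_lv 10), scored
by venetian-blind 7-fold RMSECV computed on the one-hot indicator matrix
for classification — one scalar loss for both tasks, since the decision
rule (argmax) has no differentiable loss of its own. The search exploits
NIPALS nesting: one fit per search-tree node serves all counts at that
node, so the cost is O(((max_lv+1)^(B−1)) fits per fold), and a greedy
per-block search is available to bound cost for many blocks. The all-zero
combination is excluded. Ties (within the same 1e−8 relative tolerance)
resolve to the smallest total LV count, then to the combination loading
the earliest blocks — which is what guarantees an exact duplicate of an
earlier block ends up with 0 LVs. Because every single-block combination
(k, 0, …, 0), (0, k, …, 0), … lies inside the searched grid, the selected
combination's RMSECV can never exceed the best single-preprocessing grid
point (asserted numerically).

## Workflow and pipeline

`run_sport_workflow` honors the emulated split sizes as a fraction
(train_frac = 182/273 ≈ 2:1) rather than absolute counts, so any n works.
Baselines are RAW plus each correction, each with its own CV-chosen LV
count. `run_study` orchestrates both tasks, writes CSV/JSON only, logs
one structured line per stage with shapes and timings, and records in the
manifest everything needed to re-derive the reports: seed, config hash,
train/test sample ids, selected LV combinations. Reports are derived
artifacts — predictions are serialized alongside and the tables are
recomputable from them (tested). The default permutation scope in the
pipeline is a configurable subset of baselines (RAW and SD by default):
permuting the full SPORT grid search 200 times is supported through the
same API but is rarely worth its cost for a calibration check.

## Problem sizes

Tests and the acceptance script run the study at reduced scale — 5
classes × 12–16 samples, 16–40 cm⁻¹ grids (226 to 91 wavenumbers),
max_lv 3–5 — chosen so the full suite exercises every code path,
including the exhaustive four-block grid search, at interactive
turnaround. The statistical checks (content CV, chance-level nulls,
permutation calibration) use 10–20 independent seeds. The paper-scale
defaults (273 samples, 901 wavenumbers, max_lv 10) run through the same
code in minutes via `run-study`.

## Known limitations

* The VSN weighting loop approximates the published variable-sorting
  normalization; weights agree qualitatively (signal variables
  down-weighted) but not numerically with other implementations.
* RMSECV on indicator matrices is a surrogate loss for classification;
  a misclassification-count criterion could select different LV
  combinations in borderline cases.
* The exhaustive grid is exponential in the number of blocks; beyond four
  blocks use the greedy search or a smaller cap.
* Absolute performance numbers on synthetic spectra are not comparable to
  any real-data study: the generator's artifact model is deliberately the
  one the corrections assume, which flatters all methods equally but
  keeps the comparisons between methods meaningful.
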