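# Methods

## Scope and data model

`anodpore` models the chain *anodization recipe → pore structure → drug
release* for nanoporous anodic alumina (NAA). One experiment is one record:
electrolyte (H2SO4 / H2C2O4 / H3PO4), voltage (V), temperature (°C), time
(min), measured pore diameter (nm), and optionally interpore distance,
depth, concentration, current density and measurement technique. Real
literature compilations of this kind are heterogeneous and incomplete;
the package therefore treats preprocessing (canonicalization, case-wise
deletion, encoding, standardization) as first-class, tested operations.

## Synthetic-data generator

The generator emulates the statistical structure such a compilation
exhibits, not any individual study. Its response surface is linear:

    d = b0[e] + b_V[e]·V + b_T·T + b_t·t + N(0, σ²),

truncated to the physical plausibility window (5, 350) nm by redrawing the
noise (truncation-by-resampling avoids the boundary atoms hard clipping
would create). Defaults, chosen once as the package's reference study
conditions:

| parameter | default | rationale |
|---|---|---|
| n_records | 99 | reference compilation size |
| class probabilities | 18/41, 18/41, 5/41 | composition of the per-electrolyte statistics table |
| b_V (nm/V) | 1.0 (sulphuric), 1.29 (oxalic), 1.5 (phosphoric) | literature voltage sensitivities; 1.29 is the classical oxalic rule |
| b_T (nm/°C) | −0.4 | midpoint of the −0.3…−0.5 literature band |
| b_t (nm/min) | 0 | time mainly sets pore depth, not diameter |
| σ (noise, nm) | 5 | keeps the sulphuric class SD near the literature value (~5.4 nm) once the ~4.3 nm voltage-induced spread is added |
| voltage windows (V) | 15–30 / 30–80 / 80–200 | class-typical anodization ranges |
| temperature range | 0–30 °C | chilled-electrolyte practice |
| time range | 0.4–9600 min | literature marginal range (uniform sampling; inert since b_t = 0) |
| interpore ratio | 0.35 | pore diameter ≈ 0.35 × interpore distance in self-ordered NAA |
| missing rates (T, t) | 0.118 each | with independent MCAR blanking, E[complete cases] = 99·(1−r)² ≈ 77 |

Class intercepts are solved so the class-conditional mean at the sampling
midpoints reproduces the literature class means (23.3 / 46.7 / 104 nm):
b0 = mean − b_V·mid(V) − b_T·mid(T), giving 6.8 / −18.25 / −100 nm. A
negative intercept is a regression offset, not a physical diameter; the
response stays positive over each class's voltage window.

Inputs are sampled uniformly over the per-class windows — deliberately
simpler than the skewed empirical marginals of real compilations.
Missingness is MCAR, applied only to temperature and time (diameter and
voltage are near-universally reported). What passing tests therefore show:
the pipeline recovers known coefficients, ratios and missingness structure
under clean, linear, homoscedastic conditions. What they do not show:
robustness to inter-laboratory measurement bias (SEM vs TEM vs AFM),
non-MCAR missingness, nonlinearity or reporting errors in real data.

## Surrogates

**MLR** is exact OLS (rank-checked `lstsq`), with classical standard errors
s²(XᵀX)⁻¹. Under one-hot encoding the design uses reference-cell coding
(drop the sulphuric indicator, add an intercept) to stay full-rank; the
network uses all three indicators.

**Network**: 64-32-16 ReLU funnel, linear output, trained by Adam
(lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e-8), batch size 32, max 1000 epochs, L2
penalty 1e-4, early stopping on an internal (unstratified) 15% validation
split with 50-epoch patience, seed 42 for weight init and shuffling.
Training is delegated to scikit-learn's MLPRegressor (loss = MSE, the
standard regression choice, consistent with RMSE reporting; weight init is
the library's seeded Glorot scheme; ReLU derivative at 0 taken as 0).
The fitted weights are extracted and prediction uses the package's own
forward pass, so serialized models (JSON) are self-contained; equality
with the library forward is tested.

**Encodings.** Both a 6-column one-hot encoding (default) and a 4-column
"compact" integer coding of the electrolyte are provided; the compact form
matches a literal 4-input network, the one-hot form is the conventional
treatment of an unordered category. Continuous columns are standardized
(mean 0, population SD 1) with scaler parameters fitted on training rows
only and reused for test/CV folds — no leakage; the scaler is refit inside
each CV fold.

**Cross-validation**: seeded shuffle, k = 5 near-equal folds (sizes differ
by ≤ 1), unstratified; per-fold held-out R²; aggregation reports the mean
and the **population SD** (divisor k). The population convention is pinned
by a test against published fold-score aggregates and is used consistently
in `summarize` as well. The fold-assignment seed is independent of the
network seed.

## Feature importance

Network: mean |first-layer weight| per input column. MLR: |standardized
coefficient| (intercept excluded; reference-cell indicator coefficients
used as-is, since indicators are unscaled). Indicator columns of the
electrolyte category are **summed** into one "electrolyte_type" score —
summation (rather than max or mean) preserves the normalization total —
then all scores are scaled to 100%. These are indicative proxies, not
faithful attributions (they ignore deeper layers and interactions); the
report object carries that caveat. Permutation/SHAP methods are out of
scope.

## Structure analysis

Sweeps hold two inputs fixed (defaults 10 °C, 60 min), run the
encode→predict round trip over a strictly increasing grid, and report the
mean finite-difference slope (exactly the coefficient, for an affine
model). Grids beyond the training support trigger an extrapolation
warning. Default grids: voltage 20–150 V step 5; temperature 0–30 °C
step 1. Porosity assumes an ideal hexagonal array, ε = (π/2√3)(d/D)²,
bounded by π/2√3 ≈ 0.9069 (pores merge at d = D; rejected). Loading
capacity assumes pores completely filled with drug solution at C0:
load = ε · depth · C0 (µg/cm²), with no adsorbed-layer term.

## Release kinetics

Units are percent throughout: Q(t) = K·√t with Q in % of the load and K in
% h⁻¹ᐟ². A constant quoted per unit fraction (h⁻⁰·⁵) is K/10; the
package's reference table stores percent-unit constants because only that
convention makes the tabulated t₅₀ = (50/K)² and t₉₀ = (90/K)² columns
mutually consistent. The initial release rate is defined operationally as
Q(1 h) = K (%/h); the alternative k/2 convention is emitted as a separate,
labelled column. The 30 nm reference row is internally inconsistent in its
last digit and is excluded from exact checks.

Renkin hindrance H(λ) is evaluated literally; it is 1 at λ = 0 and 0 at
λ = 1, clipped below at 0, warns above the classical validity limit
λ > 0.4, and rejects λ > 1. D_eff = D_bulk·H(λ) with λ = r_molecule/r_pore.
Defaults describe ibuprofen (206 Da, r = 0.37 nm, D_bulk = 6e-6 cm²/s) in
NAA with ε = 0.3, τ = 1.5, C0 = 100 mg/mL.

A release constant of the printed form k = D·C0·ε/τ is dimensionally
inconsistent with h⁻¹ᐟ²; the package implements the square-root form
K = s·√(D_eff·C0·ε/τ) with one calibration scale s fixed so the 75 nm
default configuration returns K = 9.5. This **mechanistic** route predicts
only a ~4% rise in K from 30 to 150 nm pores (Renkin hindrance is weak for
a 0.37 nm molecule in tens-of-nm pores), whereas the reference constants
rise by a factor ~2.06. The **empirical** route therefore fits
K = K_ref·(d/d_ref)^p once by log-log OLS to the five reference (d, K)
pairs (p ≈ 0.446, residuals ≤ ~4.3%) and reproduces that stronger
dependence, which presumably aggregates effects beyond steric hindrance
(loading, wetting, surface interactions). Neither route is privileged;
`higuchi_constant(mode=...)` selects one explicitly.

Sensitivity: t₅₀ ∝ τ/(D·C0·ε) in closed form, so a ±δ perturbation of τ
changes t₅₀ by exactly ±δ and of D or ε by 1/(1±δ)−1. The perturbation
magnitude δ is a required argument (no canonical value exists), and
perturbations that leave the valid parameter domain (e.g. ε ≥ 1) are
rejected.

## Numerical conventions and degenerate inputs

* Population SD (divisor n) everywhere a spread is aggregated.
* Standardization of a constant column warns and leaves it at zero rather
  than dividing by zero; zero-variance targets make R² undefined (NaN,
  with a warning).
* Stratified splits round the per-class test count (`round(n·fraction)`),
  keep ≥ 1 training member per class, and send singleton classes entirely
  to train with a warning.
* Report tables round to 1 decimal; all internal computation is at full
  precision. Two t₉₀ values (89.75, 66.94 h) sit on rounding boundaries
  and are compared at 0.1 h.
* Seeds: generator, missingness (derived stream), split, network and CV
  fold assignment are all explicit and independent; identical configs give
  bit-identical outputs.

## Problem sizes

The default reference study is 99 records (77 complete cases). Property
checks use: parameter recovery at n = 200 over 100 replicates (OLS ±2 SE
coverage ≥ 90%); surrogate-comparison direction at n = 77, 25 nm noise,
over 10 generator seeds (the linear model's CV mean beats the network's in
≥ 7); Monte-Carlo mean checks at n = 10⁵. These sizes were chosen to make
the stochastic assertions stable under their stated bounds.

## Known limitations

* The linear generator cannot express electrolyte-specific nonlinearity,
  voltage–temperature interactions, or the long-tailed time marginal of
  real compilations; conclusions about the network's behaviour on real
  data are correspondingly limited.
* Concentration and current density are carried in the schema but excluded
  from the model inputs (inconsistent units and sparse reporting make them
  unusable without curation); no unit auto-conversion or imputation is
  attempted.
* The release model is one-dimensional Higuchi: no burst term, no
  drug–wall adsorption, no pore-size distribution, no depth dependence of
  the release constant, cap at 100% by construction.
* Sweep confidence bands are not implemented (no principled construction
  is available for the fitted surrogates without a bootstrap, which is out
  of scope).
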