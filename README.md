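# anodpore

Process–structure–release modelling for nanoporous anodic alumina (NAA)
drug-delivery coatings.

NAA is made by electrochemically anodizing aluminium in an acidic
electrolyte, which self-organizes hexagonally packed cylindrical nanopores.
The pore diameter — the property that controls how much drug a coating
holds and how fast it releases it — depends on the anodization recipe:
electrolyte (sulphuric, oxalic or phosphoric acid), voltage, temperature
and time. `anodpore` provides, for researchers designing such coatings:

* **a synthetic-data generator** emulating a multi-decade literature
  compilation of anodization experiments (class-specific baselines, linear
  voltage/temperature response, pore–interpore coupling, case-wise
  missingness), so every downstream stage is testable without a download;
* **process→structure surrogates**: ordinary least-squares multiple linear
  regression and a 64-32-16 ReLU feed-forward network (Adam, early
  stopping), with R²/RMSE/MAE metrics, stratified train/test splitting and
  5-fold cross-validated comparison;
* **weight-based feature importance** for both surrogates, normalized to
  100% across voltage, temperature, time and electrolyte type;
* **structure analysis**: voltage/temperature response sweeps, the
  empirical d ≈ 1.29·V (nm) rule benchmark, pore–interpore regression,
  hexagonal-packing porosity ε = (π/2√3)(d/D<sub>int</sub>)² and drug
  loading capacity;
* **structure→release kinetics**: the Higuchi square-root law
  Q(t) = K·√t (Q in %, K in % h<sup>−1/2</sup>) with the pore-size
  dependence of the effective diffusivity given by the Renkin hindrance
  factor for a molecule of radius r in a cylindrical pore of radius
  r<sub>p</sub>,

  D_eff = D_bulk · (1−λ)² (1 − 2.104λ + 2.09λ³ − 0.95λ⁵),  λ = r/r_p,

  plus closed-form characteristic times t₅₀ = (50/K)², t₉₀ = (90/K)² and
  one-at-a-time sensitivity analysis.

## Worked example

```python
from anodpore.release_kinetics import release_table

print(release_table([(50.0, 8.0), (100.0, 11.0)]).to_string(index=False))
```

```
 pore_diameter_nm  K_pct_per_sqrt_h  k_fraction_units  t50_h  t90_h  initial_rate_pct_per_h  half_constant_rate_pct_per_h
             50.0               8.0               0.8   39.1  126.6                     8.0                           0.4
            100.0              11.0               1.1   20.7   66.9                    11.0                           0.6
```

Reading: with a release constant of 8 % h<sup>−1/2</sup> (50 nm pores), half
of the loaded drug has left the coating after 39.1 h and 90% after 126.6 h;
growing the pores to 100 nm (K = 11) cuts the 50%-release time to 20.7 h
and raises the first-hour release from 8% to 11% of the load. The
`k_fraction_units` column is the same constant expressed per unit fraction
instead of percent (K/10), and `half_constant_rate` is the alternative k/2
initial-rate convention.

The full pipeline — generate (or load) a dataset, preprocess, fit both
surrogates, cross-validate, rank features and tabulate release kinetics —
runs from one command and writes a CSV report bundle plus a run log with
every seed and library version:

```sh
anodpore run --out report/
anodpore generate --seed 5 --out dataset.csv
anodpore release --diameters 30,50,75,100,150 --mode empirical
anodpore sweep --data dataset.csv --electrolyte H2C2O4 --param voltage
```

On the default synthetic study (99 records, 77 complete cases, seed 42) the
linear surrogate generalizes better than the network (CV R² ≈ 0.89 vs
≈ 0.79 with the default calibration's 5 nm noise) — the expected behaviour
for a near-linear response surface at this sample size.

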