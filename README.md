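# thiolkinetics

Predictive modelling of protein oxidation — measured as free thiol (SH)
group loss — in minced chicken meat during chilled storage, for food
scientists studying shelf life and the antioxidant (or prooxidant) effect of
plant extracts added to the meat.

Free thiols on cysteine residues are lost as meat proteins oxidise, so the
SH level (expressed as percent of its day-0 value) is a quality index whose
decay can be modelled. The package implements the full modelling chain:

* **Zero-order kinetics per temperature.** At constant temperature the decay
  is linear, SH(t) = SH₀ − k·t, with SH₀ = 100% and k (%/day) estimated by
  least squares. The reaction order (0, 1 or 2) can be checked by comparing
  the linearity of SH, ln SH and 1/SH against time.
* **Arrhenius temperature dependence.** k(T) = k₀·exp(−Eₐ/(R·T)) with Eₐ in
  kJ/mol (R = 8.314×10⁻³ kJ·mol⁻¹·K⁻¹). Two estimators: the classical
  two-stage linearization (OLS of ln k on 1/T) and a global
  Levenberg–Marquardt fit of SH = 100 − k₀·exp(−Eₐ/(R·T))·t over all
  observations at once.
* **MLP regression ensemble.** Single-hidden-layer networks on one-hot
  treatment/heat-state blocks plus min-max-scaled time and temperature,
  trained full-batch by BFGS on a sum-of-squares loss; an architecture
  search keeps the five best networks by validation error and predicts with
  their mean.
* **Dummy-coded treatment regression.** SH = β₀ + Σβⱼ·1[treatment j] +
  β_T·T + β_t·t + ε with the control as the uncoded reference; t-tests at
  p ≤ 0.05 flag extracts whose slopes differ from control (positive =
  antioxidant, negative = prooxidant).
* **External validation.** Models are fitted at 4/8/16/20 °C and scored on
  the withheld 12 °C series (R², adjusted R², RMSE, predicted-vs-observed
  scatter); overlap between hold-out and fitting temperatures is a hard
  error.
* **Synthetic-data generator.** A seeded emulation of the storage study
  (14 treatments × raw/cooked, triplicates, daily sampling for 13 days at
  4/8/12 °C and 5 days at 16/20 °C) driven by the 28 published (k₀, Eₐ)
  pairs, with additive Gaussian noise (default SD 2% of initial SH).

## Worked example

Simulate the full study at the default 2% noise, fit the bay-leaf/raw cell
and validate it at the withheld temperature:

```python
import thiolkinetics as tk

ds = tk.simulate_study(tk.table2_models(), tk.paper_design(noise_sd=2.0, seed=11))
fits = tk.fit_all_temperatures(ds, "bay_leaf", "raw")   # 12 °C held out
for f in fits:
    print(f"T = {f.temperature_k:.2f} K   k = {f.k:6.3f} %/day   R^2 = {f.r2:.3f}")
params = tk.fit_arrhenius_two_stage(fits)
print(f"Ea = {params.ea:.2f} kJ/mol   k0 = {params.k0:.3g} 1/day   R^2 = {params.r2:.4f}")
model = tk.KineticModel("bay_leaf", "raw", params, fitted_temperatures_c=(4, 8, 16, 20))
holdout = ds.select("bay_leaf", "raw", temperatures_c=[12.0])
report = tk.external_validate(model, holdout)
print(f"hold-out 12 C: R^2 = {report.r2:.3f}, RMSE = {report.rmse:.2f}% (n = {report.n})")
```

Output:

```
T = 277.15 K   k =  2.900 %/day   R^2 = 0.965
T = 281.15 K   k =  4.421 %/day   R^2 = 0.987
T = 289.15 K   k =  9.260 %/day   R^2 = 0.995
T = 293.15 K   k = 12.750 %/day   R^2 = 0.992
Ea = 62.54 kJ/mol   k0 = 1.81e+12 1/day   R^2 = 0.9991
hold-out 12 C: R^2 = 0.994, RMSE = 2.03% (n = 42)
```

The per-temperature rate constants rise with temperature; the Arrhenius
regression recovers an activation energy close to the generating 63.75
kJ/mol, and the model predicts the never-seen 12 °C series to within about
2% RMSE.

The same workflow is available from the shell:

```sh
thiolkinetics simulate --output study.csv --seed 11
thiolkinetics fit --input study.csv --output-dir out/
thiolkinetics validate --input study.csv --models out/arrhenius_params.csv --output-dir out/
thiolkinetics ann --input study.csv --output-dir out/ --seed 11
thiolkinetics mlr --input study.csv --output out/treatment_effects.csv
```

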