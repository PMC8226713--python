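# Methods

## The decay model

Protein oxidation in minced meat is tracked through the loss of free thiol
(SH) groups, expressed as percent of the day-0 level so that every
(treatment, heat state, temperature) group starts at SH₀ = 100%. Two
assumptions define the kinetic model:

1. **Zero order in SH** — at constant temperature the loss rate is constant,
   SH(t) = SH₀ − k·t. Order selection (`select_order`) confirms this on a
   given series by comparing the straight-line R² of SH, ln SH and 1/SH
   against time; ties break toward the lower order, so short series default
   to zero order.
2. **Arrhenius temperature dependence** — k(T) = k₀·exp(−Eₐ/(R·T)) with the
   gas constant R = 8.314×10⁻³ kJ·mol⁻¹·K⁻¹, so Eₐ is in kJ/mol and k₀ in
   day⁻¹ on the percent scale. In a food matrix this is an empirical
   temperature-sensitivity summary, not a single-reaction barrier: many
   reactions contribute to thiol loss, and Eₐ should be read as "how strongly
   storage temperature accelerates the decay".

Temperatures are stored in °C and converted internally with
T(K) = T(°C) + 273.15, never integer-rounded.

## Estimators

**Two-stage (default headline).** Per-temperature OLS of SH on t gives k at
each temperature (the free-intercept fit is the default; a fixed-intercept
mode pins SH₀ = 100 and estimates only the slope). Then OLS of ln k on 1/T
gives Eₐ = −slope·R and k₀ = exp(intercept). Replicates enter as individual
points by default — more data-efficient than fitting per-day means — with an
`average_replicates` option for mean-based fitting; on a balanced noiseless
design the two are identical.

**Global Levenberg–Marquardt.** All (t, T, SH) observations of a group are
fitted at once by nonlinear least squares of SH = SH₀ − exp(ln k₀ −
Eₐ/(R·T))·t. The fit is parameterized in (ln k₀, Eₐ) because k₀ spans
roughly 10⁵–10²² across the study's cells and would otherwise overflow the
Jacobian scaling; the log-parameterization also keeps k₀ positive by
construction. Initialization comes from the two-stage estimate when
available; otherwise Eₐ starts at 60 kJ/mol (mid-range of the published
estimates) with ln k₀ chosen to match the mean observed decay rate.
Tolerances are xtol = ftol = gtol = 1e-14 with a 500-evaluation budget;
non-convergence raises a failure signal carrying the last iterate.

The two estimators coincide exactly on noiseless zero-order data and agree
closely under realistic noise; the CLI `fit` command reports both. The R²
attached to the two-stage parameters is that of the ln k vs 1/T regression,
the one attached to the global parameters is observed-vs-fitted SH — both
are labelled in the registry because the two definitions answer different
questions. Per-group goodness is also summarized as ΣR², the sum of the four
per-temperature R² values (range 0–4).

## Synthetic data: what it emulates and what it does not

`synthetic` generates the full factorial study: 14 treatments × 2 heat
states, triplicates, daily sampling over 13 days at 4/8/12 °C and 5 days at
16/20 °C (1512 observations per heat state, 4536 in total), driven by the
28 published (k₀, Eₐ) pairs shipped as a packaged CSV. Noise is additive
Gaussian on the percent scale, homoscedastic, default SD 2% — of the order
of the triplicate scatter implied by published per-temperature RMSE values —
and fully determined by one seed shared across the study so that equal seeds
give byte-identical CSVs. Simulated values below zero are kept by default so
estimators see the model's true support (a clamp-at-zero option exists).

The generator reproduces the *assumed* data-generating process, so passing
recovery tests shows the estimation chain is correct and unbiased under
that process. It does not reproduce features real storage data may have:
heteroscedastic or autocorrelated replicate error, day-0 normalization
noise, departures from strict zero-order decay, or treatment-dependent
noise levels. Conclusions about real meat require the real measurements.

## The MLP ensemble

Features: 14-wide treatment one-hot block, 2-wide heat-state block, time and
temperature min-max scaled to [0, 1] on the fitted data — 18 inputs. The
target is SH% min-max scaled to [0, 1]. Networks have one hidden layer
(tanh, logistic or exponential activation) and one output unit; bounded
output activations are mapped affinely onto the scaled target range
(tanh z → (tanh z + 1)/2, logistic z → σ(z), linear z → z) so every family
can cover it. Weights start uniform(−0.5, 0.5) from the spec seed and are
trained full-batch by BFGS (analytic gradients) on the sum-of-squares loss;
the default iteration cap is 300, configurable, and a cap of 0 returns the
seeded initial network for inspection.

The data are split 70:15:15 into training/validation/test by a seeded
permutation with largest-remainder rounding. The architecture search trains
every candidate in the grid, ranks by validation sum-of-squares error (ties
break by grid order, making duplicate candidates stable) and retains the
best five; the ensemble prediction is the arithmetic mean of the five
member predictions, de-scaled to percent. Averaging five squared-error
learners can never be worse than the worst member and is typically better
than the median member — the usual variance-reduction argument.

## Treatment-effect regression

Within one heat state, SH% is regressed on an intercept, 13 treatment
indicators (control = uncoded reference), storage temperature (°C) and time
(days), pooled over all temperatures and times. The raw scales are kept so
slopes read directly as %/°C and %/day. Inference is classical OLS
(homoscedastic SEs, two-sided t-tests, boundary-inclusive significance at
p ≤ alpha, default 0.05). Raw and cooked meat are fitted separately. Note
the linear pooled model is deliberately simpler than the kinetic one — it
ignores the k×t interaction structure — so its residual variance contains
lack-of-fit; its purpose is ranking treatments against control, not
prediction.

## Validation metrics

R² = 1 − SSE/SST with SST about the observed mean; adjusted R² =
1 − (1−R²)(n−1)/(n−p−1) with p = 2 for kinetic models (k₀, Eₐ) and p = the
total weight count for MLP ensembles; RMSE uses denominator n (not n−p),
and the report records that convention. External validation refuses to
score a predictor on any temperature it declares among its fitting
temperatures.

## Numerical choices and degenerate inputs

* Order-selection ties use a 1e-12 R² tolerance toward the lower order.
* Isothermal fits require ≥ 2 distinct time points; Arrhenius fits ≥ 2
  distinct temperatures with positive rate constants; the global fit raises
  an identifiability error on single-temperature data.
* Zero observed variance makes R² undefined and raises rather than
  returning NaN.
* Simulation problem sizes in the test suite: the full 28-cell noiseless
  round trip runs once; stochastic recovery uses 200 replications per model
  at SD 2% and 60 per noise level for the consistency check; the
  false-flag-rate simulation uses 400 studies. These sizes give Monte-Carlo
  standard errors comfortably below the margins being checked.

## Known limitations

* Only the Arrhenius form is implemented for temperature dependence (no
  Eyring or WLF alternatives), and no profile-likelihood confidence
  intervals are provided for (k₀, Eₐ).
* The published per-network accuracy values of the original ANN analysis
  depend on the experimental measurements and the original trainer and are
  not reproduction targets; the ensemble here is validated structurally
  (fit quality on synthetic data, selection and averaging contracts).
* The MLR assumes independent homoscedastic errors; repeated measures on
  the same sample over time are not modelled (no mixed effects or
  autocorrelation).
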