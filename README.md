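# biodegkin

Kinetic modelling of polymer biodegradation from weight-loss time series.

When a biodegradable polymer — for instance a sugar-based glycopolymer —
degrades in a microbial environment, the process is tracked by the weight
loss of the sample, `w(t) = 100 · (m(0) − m(t)) / m(0)` in %, measured at a
handful of times (days). Sugar-skeleton polymers with a synthetic
(meth)acrylate network typically degrade in **two phases**: the sugar
skeleton is consumed quickly, then — after a lag while the microbial
consortium adapts to the synthetic carbon source — the acrylate network is
degraded until saturation. This package is built around an empirical model
of that profile: two exponential saturation terms separated by a dead time,

```
w(t) = w0 + w1∞ · [1 − exp(−t/T1)] + w2∞ · [1 − exp(−(t−τ)/T2)] · σ(t−τ)
```

with weight-loss potentials `w1∞, w2∞` (%), time constants `T1, T2`
(days), dead time `τ` (days), the unit step `σ`, and an optional baseline
offset `w0` (default 0, used e.g. for log-CFU bacterial growth curves that
start at a nonzero level).

The package is aimed at experimentalists fitting degradation (or
growth-curve-shaped) data and provides:

- **Five closed-form models**: the two-phase dead-time model above plus
  the classical single-exponential, modified Gompertz, logistic, and
  Gordon–Govind–Green–Imam–Shogren comparison models.
- **scikit-learn-style fitting** (`DoubleExpDelayRegressor` and friends):
  nonlinear least squares (trust-region damped, finite-difference
  Jacobian, box constraints), with an automatic initial guess that
  transcribes the classical graphical construction (angular point → dead
  time, plateaus → potentials, log-linear subtangents → time constants).
- **Exogenous dynamic systems**: the model regenerated as the free
  response of a four-state linear system with dead time (and the logistic
  curve as a first-order rate law), integrated numerically and verified
  against the closed forms.
- **A goodness-of-fit panel** (RMSE, MSE, R², Pearson R, relative
  absolute error) and per-point residual tables.
- **Reference datasets**: three published weight-loss tables
  (`bioreactor_wastewater`, `bioreactor_bega`, `gordon_tropical`) with
  their reference model parameters, bundled as validated fixtures.
- **Synthetic data generation** with seeded Gaussian noise, and a
  **command-line interface** (`biodegkin fit / eval / simulate / compare /
  synth`) with logged, reproducible runs.

## Worked example

```python
import numpy as np
from biodegkin import (DoubleExpDelayRegressor, fit_all_models,
                       indicator_panel, load_fixture)

fx = load_fixture("bioreactor_wastewater")   # glycopolymer, 17 points
reg = DoubleExpDelayRegressor(init=fx.initial_guess)
reg.fit(fx.series_corrected)
print(np.round(reg.params_.to_array(), 4))
print(round(reg.result_.rmse, 4))
```

prints

```
[42.3229  2.2813  6.6399 35.1542  0.6441]
0.5378
```

i.e. the first (sugar-skeleton) phase releases `w1∞ ≈ 42.3%` with a
2.3-day time constant; after a dead time of `τ ≈ 6.6` days the second
(acrylate) phase adds `w2∞ ≈ 35.2%` with a 0.64-day time constant, and the
fit tracks the measured points to an RMSE of about 0.54 weight-loss
percentage points. Comparing models on the same data,

```python
for e in fit_all_models(fx.series):
    print(f"{e.model_name:18s} rmse={e.panel.rmse:7.4f}  r={e.panel.r:.4f}")
```

```
double_exp_delay   rmse= 0.7505  r=0.9996
gompertz           rmse= 5.1596  r=0.9799
exponential        rmse= 5.5917  r=0.9765
logistic           rmse=14.7835  r=0.9742
```

the two-phase dead-time model is the clear best description of the
two-arc profile.

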