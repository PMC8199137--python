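# Methods

## The model

The package models biodegradation kinetics through the *characteristic
function* of the process: the weight-loss curve w(t) itself, rather than a
mechanistic description of the microbial community or mass transport. The
core model is a sum of two exponential saturation terms separated by a
dead time,

    w(t) = w0 + w1_inf (1 − e^{−t/T1}) + w2_inf (1 − e^{−(t−τ)/T2}) σ(t−τ),

a five-parameter vector P = (w1_inf, T1, τ, w2_inf, T2) plus an optional
fixed baseline w0. The two terms map onto the two-phase degradation of
sugar-skeleton glycopolymers (fast loss of the saccharidic skeleton, then
slower degradation of the (meth)acrylate network once the microorganisms
have adapted to it — the dead time). Geometrically each time constant is
the subtangent cut on the asymptote of its rising arc. The model's
supremum is w0 + w1_inf + w2_inf; it is continuous at t = τ because the
gated term vanishes there, and we fix the (observationally neutral)
convention σ(0) = 1. Time is in days and weight loss in percent
throughout; there is no unit-conversion layer.

Four classical comparison models are provided: single-exponential
saturation, the modified Gompertz curve, the logistic curve, and the
16-coefficient Gordon–Govind–Green–Imam–Shogren form. The logistic model
is implemented exactly as conventionally written for these comparisons,
w = W_inf/(1 + e^{−kt}); note it starts at W_inf/2, not 0, which is one
reason it ranks poorly on degradation data that starts at zero. The
baseline offset w0 makes nonzero-origin processes (e.g. bacterial growth
measured as log CFU/mL, starting at the inoculum level) representable
without a separate model type.

## Fitting

Parameters are estimated by nonlinear least squares on the raw residuals
(unweighted). The optimiser is scipy's trust-region reflective
`least_squares` — a damped iterative least-squares scheme — with a
three-point finite-difference Jacobian (relative step 1e-6), relative
convergence tolerances of 1e-8 on the cost, parameters and gradient, and
a cap of 1000 iterations per parameter. Box constraints keep time
constants ≥ 1e-6 day and potentials and dead time nonnegative; all
published estimates lie strictly inside these bounds. The dead time τ is
optimised as a continuous variable although the objective is only
piecewise-smooth in it (the step gate crosses sample times); the
trust-region damping absorbs the local Jacobian discontinuities, and in
practice τ converges to interior optima without difficulty.

Estimates of this model are **not unique** in the strict sense: restarts
from perturbed initial values converge to parameter vectors that differ
in the third or fourth digit at essentially the same residual norm
(observed spread ~1e-11 relative in SSE). Comparisons across fits should
therefore be made on the residual norm, which is what the test suite
asserts across restarts. The Gordon model is worse: jointly scaling one
block's coefficients and its potential leaves w(t) exactly unchanged
(gauge freedom), so for it only the fitted curve — not the coefficient
vector — is recoverable. It is fitted only on explicit request with
user-supplied initial values; no automatic initializer is offered for it.

### Automatic initial guess

The initializer transcribes the graphical construction a practitioner
would do by hand on the plotted curve:

1. *Dead time*: the angular point between the two rising arcs is the
   interior sample with the largest positive increase of the discrete
   slope; its abscissa estimates τ. If the slope never increases the
   series looks single-exponential and a `DegenerateSecondArcError`
   advises the exponential model instead (also raised when fewer than two
   samples follow the angular point).
2. *First potential*: the value at the angular-point sample (the level
   the first arc has reached when the second phase starts).
3. *Time constants*: for a saturating exponential the distance to the
   asymptote decays as e^{−t/T}, so T is recovered as −1/slope of a
   linear regression of ln(asymptote − w) on t over the samples of that
   arc — the discrete counterpart of reading the subtangent off the
   graph. Samples within 2% of the asymptote are dropped (they carry
   mostly noise); a span-based fallback (arc length / 3) covers arcs with
   too few informative points. A plain max-discrete-slope quotient was
   tried first and rejected: on coarse schedules it underestimates the
   initial slope of a fast second arc severalfold and lands outside the
   useful neighbourhood of the optimum.
4. *Second potential*: last observed value minus the first potential,
   floored at a small positive value (1e-3%).

Under measurement noise the largest slope increase occasionally sits on a
noise spike in the plateau rather than on the true phase break. The
regressor therefore runs a short multistart when initialised
heuristically: the top 5 candidate angular points are each used as a
starting dead time and the fit with the smallest residual norm wins
(`n_starts` parameter). Each start costs ~10 ms on typical series. With
explicit initial parameters exactly one start is used, reproducing the
classical single-start workflow.

## Exogenous dynamic systems

The same profile can be generated as the free response of a small dynamic
system — an *exogenous* signal generator in the control-theoretic sense,
not a physical model. For the two-phase model this is a four-state linear
system with dead time: x1, x3 constant at 1; x2, x4 decaying from 1 with
rates 1/T1 and 1/T2; output
w = w0 + w1_inf (x1 − x2)(t) + w2_inf (x3 − x4)(t − τ) · σ(t − τ).
The system is formally infinite-dimensional because of the delay, but
since x3 and x4 have closed-form exponential histories the delayed pair
is evaluated by time-shifting the integrator's dense output rather than
running a general delay-differential solver; for this structure the two
treatments are indistinguishable (verified < 1e-8 against the closed
form). The state equations are integrated with DOP853 at abs/rel
tolerance 1e-10, with the step size capped at the output spacing — once
the fast state has decayed, an uncapped controller takes steps long
enough that the dense interpolant visibly degrades on the fast-decay tail
(errors ~1e-5 were observed; the cap brings agreement with the closed
form to ~1e-10). Because the solution is produced by one adaptive pass
and then sampled, halving the output spacing leaves values at common grid
points essentially unchanged.

The logistic curve corresponds to the first-order rate law
ẇ = k·w·(1 − w/W_inf). Its printed second-order-in-w form with w(0) = 0
admits only the trivial solution w ≡ 0 (the origin is a fixed point), so
the simulator requires a caller-supplied w_init ∈ (0, W_inf]; started
from W_inf/2 it coincides with the closed-form logistic curve, and
started at W_inf it stays at the plateau.

## Goodness-of-fit panel

With residuals d_i = measured − predicted over n points: MSE = Σd²/n
(population form, ÷n not ÷(n−1) — the divisor recovered from the
published indicator rows), RMSE = √MSE, R = Pearson correlation of
measured vs predicted, R² = 1 − Σd²/SST, and the relative absolute error
rAE = (Σ|d|/n)/max(measured). The rAE definition is reverse-engineered
from the published rows (mean absolute residual over the series maximum
reproduces the printed value to the printed precision); it is not a
standard formula and is documented as such. All points enter the panel,
including a leading (0, 0) observation. A zero-variance measured series
makes R and R² undefined; the panel returns NaN with a
`correlation_defined=False` flag rather than raising. Some published
indicator values are *not* reproducible from their own printed residuals
(determination coefficients above 1, and one RMSE inconsistent with its
residual row by a factor ~2.3); those rows are excluded as reference
targets and replaced by the definitional identities and scale-behaviour
property tests.

## Reference datasets and known print defects

Three published weight-loss tables ship as JSON fixtures with their
reference model parameters; a hash test guards against silent drift. Two
mutually consistent typesetting defects were identified in the
wastewater-bioreactor table: the measured value at t = 12 days is a 9/6
digit typo (79.687 printed for 76.687 — the printed residual −0.5172
equals 76.687 − CW(12) exactly, and refitting from the published starting
vector reproduces the published parameter vector within 0.15 per
component only with the corrected value, versus 0.70 off with the value
as printed), and the model-value/residual entries of the t = 9 column
duplicate those of t = 12 (direct evaluation at t = 9 gives 75.6287).
Fixtures store the series as printed *and* a `values_corrected` variant;
fit-reproduction workflows use the corrected series, evaluation
comparisons skip the duplicated column. For the tropical-water dataset
two of the nine points are visual interpolations added to stabilise the
regression; which two is marked only by shading in the source figure, so
the flags (t = 28 and t = 70, the two samples off the round-number
sampling schedule) are a best-effort reconstruction recorded in the
fixture notes. Interpolated-point augmentation is deliberately not
automated — the fixture carries the augmented points pre-inserted and
flagged.

## Synthetic data

`generate_synthetic` draws w_i = model(t_i; θ) + ε_i with
ε ~ N(0, noise_sd²), untruncated (high-noise series may dip below 0 near
t = 0; the fitter tolerates this), from a seeded generator — the same
seed always reproduces the same series. The recovery experiments use a
well-conditioned two-phase truth (40, 2, 10, 40, 3) sampled every half
day over 30 days — a dense, regular schedule resembling the bioreactor
experiments but idealised: real series are shorter (9–17 points),
irregular, and their noise is neither Gaussian nor homoscedastic, and can
include systematic effects (sample handling, drying) no i.i.d. noise
model captures. Passing recovery tests therefore demonstrate correctness
of the estimator under the stated noise model, not guaranteed parameter
accuracy on arbitrary experimental data. Noise of 1% absolute corresponds
to the residual scale of the bioreactor fits (RMSE 0.5–1.5%).

## Numerical choices and limitations

- The gated second term clamps its exponent at 0 for t < τ before
  exponentiating, so tiny T2 values cannot overflow on gated-out points.
- Ranking ties in the model comparison break toward the model with fewer
  free parameters.
- Model evaluation accepts scalars or grids; grid evaluation is
  elementwise identical to repeated scalar evaluation.
- CSV I/O is strict (header `t,w`, '.' decimal, no locale handling,
  errors name the offending line); numeric output uses 6 significant
  digits, matching the precision of the published tables.
- No uncertainty quantification (confidence intervals) and no
  information-criterion model selection are provided; comparisons use
  the indicator panel only. Distributed-parameter (PDE) and mechanistic
  microbial-growth modelling are out of scope, as are global optimisers
  (genetic algorithms, PSO) — the least-squares fit with the graphical
  initializer covers the intended data scale.
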