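"""Nonlinear least-squares fitting of kinetic weight-loss models.

The estimators follow the scikit-learn protocol: construct with
hyper-parameters, ``fit(t, w)``, then ``predict(t)``; fitted state lives in
trailing-underscore attributes (``params_``, ``result_``).  Module-level
functions (:func:`fit_model`, :func:`fit_all_models`,
:func:`heuristic_init_double_exp`) are thin wrappers for script use.

Fitting minimises the sum of squared residuals sum_i (w_i - w(t_i; P))^2
with a trust-region damped least-squares iteration and a finite-difference
Jacobian (central differences), subject to box constraints keeping time
constants positive and potentials nonnegative.  The dead time ``tau`` of the
double-exponential model is optimised as a continuous variable even though
the objective is only piecewise-smooth in it (the step gate moves across
sample points); the trust-region damping absorbs the resulting Jacobian
discontinuities.  Estimates are not unique in general — restarting from a
perturbed initial guess can return slightly different parameters at
essentially the same residual norm — so downstream comparisons should be
made on the residual norm, not on parameter identity.

The automatic initial guess for the double-exponential model is a discrete
transcription of the graphical construction used in practice: locate the
angular point between the two rising arcs (dead time), read the two plateau
levels off the data, and recover each time constant from the subtangent of
its arc via a log-linear fit of the distance to the asymptote.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .indicators import GoodnessOfFit, indicator_panel
from .models import (
    MODELS,
    DoubleExpDelayParams,
    ExponentialParams,
    GompertzParams,
    GordonParams,
    LogisticParams,
    ModelSpec,
    get_model,
)
from .series import WeightLossSeries

__all__ = [
    "FitResult",
    "InitialGuess",
    "ComparisonEntry",
    "DegenerateSecondArcError",
    "FitFailureError",
    "heuristic_init_double_exp",
    "heuristic_init_exponential",
    "heuristic_init_gompertz",
    "heuristic_init_logistic",
    "fit_model",
    "fit_all_models",
    "ExponentialRegressor",
    "GompertzRegressor",
    "LogisticRegressor",
    "GordonRegressor",
    "DoubleExpDelayRegressor",
    "REGRESSORS",
]


class DegenerateSecondArcError(ValueError):
    """No usable second arc after the detected angular point.

    Raised by the automatic initializer when fewer than two samples follow
    the detected dead time, or when the series shows no upward break in
    slope at all; a single-exponential fit is the appropriate fallback.
    """


class FitFailureError(RuntimeError):
    """The optimiser produced a non-finite model value; carries the last iterate."""

    def __init__(self, message: str, last_params=None):
        super().__init__(message)
        self.last_params = last_params


@dataclass(frozen=True)
class InitialGuess:
    """A starting parameter record plus its provenance ('user' or 'heuristic')."""

    params: object
    provenance: str = "user"


@dataclass(frozen=True)
class FitResult:
    """Outcome of one model fit on one series.

    ``residuals`` are measured minus predicted, in %, one per sample;
    ``sse`` is their sum of squares.
    """

    model_name: str
    params: object
    initial_params: object
    residuals: np.ndarray
    sse: float
    n_iter: int
    converged: bool
    message: str = ""

    @property
    def rmse(self) -> float:
        return float(np.sqrt(self.sse / self.residuals.size))


# ---------------------------------------------------------------------------
# automatic initial guesses
# ---------------------------------------------------------------------------

def _segment_slopes(t: np.ndarray, w: np.ndarray) -> np.ndarray:
    return np.diff(w) / np.diff(t)


def _log_linear_time_constant(
    t: np.ndarray, w: np.ndarray, asymptote: float, fallback: float
) -> float:
    """Time constant from ln(asymptote - w) ~ t regression (subtangent estimate).

    For a saturating exponential the distance to the asymptote decays as
    exp(-t/T), so the slope of the log-distance over time is -1/T.  Points
    too close to the asymptote (within 2% of it) are dropped as they carry
    mostly noise; if fewer than two informative points remain the fallback
    is returned.
    """
    gap = asymptote - w
    ok = gap > max(1e-9, 0.02 * abs(asymptote))
    if ok.sum() < 2:
        ok = gap > 1e-9
    if ok.sum() < 2:
        return fallback
    x, y = t[ok], np.log(gap[ok])
    slope = np.polyfit(x, y, 1)[0]
    if slope >= -1e-12:
        return fallback
    return float(-1.0 / slope)


def _angular_candidates(t: np.ndarray, w: np.ndarray, k: int) -> list[int]:
    """Indices of up to k interior samples with the largest positive slope
    increase (candidate angular points), each with >= 2 samples after it."""
    slopes = _segment_slopes(t, w)
    curvature = np.diff(slopes)  # at interior samples t[1:-1]
    order = np.argsort(curvature)[::-1]
    out: list[int] = []
    for j in order:
        if curvature[j] <= 0:
            break
        i = int(j) + 1
        if (t > t[i]).sum() < 2:
            continue
        out.append(i)
        if len(out) == k:
            break
    return out


def _guess_from_angular_point(series: WeightLossSeries, k: int) -> "InitialGuess":
    t, w = series.times, series.values
    tau = float(t[k])
    w1_inf = float(w[k])
    if w1_inf <= 0:
        w1_inf = max(float(np.max(w[: k + 1])), 1e-3)
    first = t < tau
    T1 = _log_linear_time_constant(
        t[first], w[first], w1_inf, fallback=max(tau / 3.0, 1e-3)
    )
    total = float(w[-1])
    w2_inf = max(total - w1_inf, 1e-3)
    after = t > tau
    span = float(t[-1] - tau)
    T2 = _log_linear_time_constant(
        t[after], w[after], total, fallback=max(span / 3.0, 1e-3)
    )
    params = DoubleExpDelayParams(
        w1_inf=w1_inf, T1=max(T1, 1e-6), tau=tau, w2_inf=w2_inf, T2=max(T2, 1e-6)
    )
    return InitialGuess(params=params, provenance="heuristic")


def heuristic_init_candidates(
    series: WeightLossSeries, n_candidates: int = 5
) -> list["InitialGuess"]:
    """Starting guesses for the top candidate angular points, best first.

    Under measurement noise the largest discrete slope increase can sit on
    a noise spike rather than on the true phase break, so the fitter tries
    each candidate and keeps the best resulting fit (see
    :class:`DoubleExpDelayRegressor`).
    """
    t, w = series.times, series.values
    if len(series) < 5:
        raise ValueError("heuristic initialization needs at least 5 points")
    if not w[-1] > w[0]:
        raise ValueError("heuristic initialization needs a rising profile")
    idx = _angular_candidates(t, w, n_candidates)
    if not idx:
        slopes = _segment_slopes(t, w)
        if np.diff(slopes).size == 0 or np.max(np.diff(slopes)) <= 0:
            raise DegenerateSecondArcError(
                "no angular point (slope never increases); the series looks "
                "single-exponential — fit the exponential model instead"
            )
        raise DegenerateSecondArcError(
            "fewer than 2 samples after every candidate angular point; the "
            "second arc is unresolvable — fit the exponential model instead"
        )
    return [_guess_from_angular_point(series, i) for i in idx]


def heuristic_init_double_exp(series: WeightLossSeries) -> InitialGuess:
    """Automatic five-parameter starting guess for the double-exponential model.

    Transcribes the graphical construction:

    1. *Dead time*: the angular point between the two rising arcs is the
       interior sample where the discrete slope increases the most (largest
       positive second difference of w over t); its abscissa estimates tau.
    2. *First potential*: the value at the angular-point sample, read as the
       plateau the first arc has reached when the second phase starts.
    3. *T1*: subtangent of the first arc, via log-linear regression of
       ln(w1_inf - w) over the samples before the angular point.
    4. *Second potential*: last observed value minus w1_inf (floored at a
       small positive value).
    5. *T2*: subtangent of the second arc, same regression against the
       total plateau over the samples after the angular point.

    Raises
    ------
    DegenerateSecondArcError
        If no slope increase exists (single-arc, e.g. pure exponential
        shape) or fewer than two samples follow the angular point.
    """
    return heuristic_init_candidates(series, n_candidates=1)[0]


def heuristic_init_exponential(series: WeightLossSeries) -> InitialGuess:
    """Plateau from the last sample; T from the 63.2%-of-plateau crossing."""
    t, w = series.times, series.values
    W_inf = max(float(w[-1]), 1e-3)
    target = (1.0 - np.exp(-1.0)) * W_inf
    above = np.nonzero(w >= target)[0]
    if above.size and above[0] > 0:
        i = above[0]
        # linear interpolation of the crossing time
        f = (target - w[i - 1]) / (w[i] - w[i - 1]) if w[i] != w[i - 1] else 0.0
        T = float(t[i - 1] + f * (t[i] - t[i - 1]))
    else:
        T = float(t[-1] - t[0]) / 3.0
    return InitialGuess(
        ExponentialParams(W_inf=W_inf, T=max(T, 1e-6)), provenance="heuristic"
    )


def heuristic_init_gompertz(series: WeightLossSeries) -> InitialGuess:
    """Plateau from the last sample; R_m from the steepest segment; lag from
    the zero-crossing of the tangent there."""
    t, w = series.times, series.values
    W_inf = max(float(w[-1]), 1e-3)
    slopes = _segment_slopes(t, w)
    i = int(np.argmax(slopes))
    R_m = max(float(slopes[i]), 1e-3)
    t_mid = 0.5 * (t[i] + t[i + 1])
    w_mid = 0.5 * (w[i] + w[i + 1])
    lam = max(float(t_mid - w_mid / R_m), 0.0)
    return InitialGuess(
        GompertzParams(W_inf=W_inf, R_m=R_m, lam=lam), provenance="heuristic"
    )


def heuristic_init_logistic(series: WeightLossSeries) -> InitialGuess:
    """Plateau from the last sample; k from the steepest observed slope
    (max logistic slope is k W_inf / 4)."""
    t, w = series.times, series.values
    W_inf = max(float(w[-1]), 1e-3)
    s_max = max(float(np.max(_segment_slopes(t, w))), 1e-6)
    k = 4.0 * s_max / W_inf
    return InitialGuess(LogisticParams(W_inf=W_inf, k=k), provenance="heuristic")


_HEURISTICS = {
    "exponential": heuristic_init_exponential,
    "gompertz": heuristic_init_gompertz,
    "logistic": heuristic_init_logistic,
    "double_exp_delay": heuristic_init_double_exp,
}


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _as_1d_times(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim == 2 and t.shape[1] == 1:  # sklearn-style column input
        t = t[:, 0]
    if t.ndim != 1:
        raise ValueError("t must be 1-d (or a single-column 2-d array)")
    return t


class _KineticRegressorBase(RegressorMixin, BaseEstimator):
    """Shared fit/predict machinery for all kinetic-curve estimators.

    Parameters
    ----------
    init : 'heuristic', parameter record, mapping, sequence or InitialGuess
        Starting point for the optimisation.  'heuristic' derives one from
        the data (not available for the Gordon model).
    bounds : bool
        Enforce the model's box constraints (time constants positive,
        potentials nonnegative) during optimisation.
    tol : float
        Relative convergence tolerance on the residual norm and parameters.
    max_iter : int
        Cap on optimiser iterations.
    """

    model_name: str = ""  # set by subclasses

    def __init__(self, init="heuristic", bounds=True, tol=1e-8, max_iter=1000):
        self.init = init
        self.bounds = bounds
        self.tol = tol
        self.max_iter = max_iter

    # -- subclass hooks ----------------------------------------------------
    def _box(self, spec: ModelSpec):
        n = spec.n_free
        return (np.full(n, -np.inf), np.full(n, np.inf))

    def _make_params(self, spec: ModelSpec, x: np.ndarray):
        return spec.params_cls.from_array(x)

    # ----------------------------------------------------------------------
    def _resolve_init(self, spec: ModelSpec, series: WeightLossSeries):
        init = self.init
        if isinstance(init, InitialGuess):
            return init
        if isinstance(init, str):
            if init != "heuristic":
                raise ValueError(f"unknown init mode {init!r}")
            try:
                fn = _HEURISTICS[spec.name]
            except KeyError:
                raise ValueError(
                    f"no automatic initializer for the {spec.name!r} model; "
                    "supply explicit initial parameters"
                ) from None
            return fn(series)
        if isinstance(init, spec.params_cls):
            return InitialGuess(init, provenance="user")
        if isinstance(init, Mapping):
            return InitialGuess(spec.params_cls.from_dict(dict(init)), "user")
        arr = np.asarray(init, dtype=float)
        return InitialGuess(self._make_params(spec, arr), "user")

    def fit(self, t, w=None):
        """Fit the model to observations.

        Accepts either ``fit(series)`` with a :class:`WeightLossSeries`,
        or ``fit(t, w)`` with arrays (t may be an (n, 1) feature column).
        """
        if isinstance(t, WeightLossSeries):
            series = t
        else:
            series = WeightLossSeries(_as_1d_times(t), np.asarray(w, dtype=float))
        spec = get_model(self.model_name)
        if len(series) < spec.n_free:
            raise ValueError(
                f"series has {len(series)} points but the {spec.name} model "
                f"has {spec.n_free} free parameters (underdetermined)"
            )

        best = None
        last_exc: Optional[Exception] = None
        for guess in self._initial_guesses(spec, series):
            try:
                res = self._run_solver(spec, series, guess)
            except FitFailureError as exc:
                last_exc = exc
                continue
            if best is None or res[0].cost < best[0].cost:
                best = (*res, guess)
        if best is None:
            raise last_exc if last_exc is not None else FitFailureError(
                "no starting point produced a fit")
        res, params, residuals, guess = best
        self.params_ = params
        self.initial_params_ = guess.params
        self.n_iter_ = int(res.nfev)
        self.converged_ = bool(res.status > 0)
        self.sse_ = float(np.sum(residuals**2))
        self.result_ = FitResult(
            model_name=spec.name,
            params=params,
            initial_params=guess.params,
            residuals=residuals,
            sse=self.sse_,
            n_iter=self.n_iter_,
            converged=self.converged_,
            message=str(res.message),
        )
        return self

    def _initial_guesses(self, spec: ModelSpec, series: WeightLossSeries):
        return [self._resolve_init(spec, series)]

    def _run_solver(self, spec: ModelSpec, series: WeightLossSeries,
                    guess: InitialGuess):
        x0 = guess.params.to_array()
        lo, hi = self._box(spec) if self.bounds else (
            np.full(x0.size, -np.inf), np.full(x0.size, np.inf))
        x0 = np.clip(x0, lo, hi)
        tt, ww = series.times, series.values
        fixed = self._fixed_fields(guess.params)

        def resid(x):
            p = self._make_params_fixed(spec, x, fixed)
            r = spec.evaluate(p, tt) - ww
            if not np.all(np.isfinite(r)):
                raise FitFailureError(
                    "model value became non-finite during iteration",
                    last_params=p,
                )
            return r

        res = least_squares(
            resid,
            x0,
            jac="3-point",
            bounds=(lo, hi),
            method="trf",
            ftol=self.tol,
            xtol=self.tol,
            gtol=self.tol,
            max_nfev=self.max_iter * max(x0.size, 1),
            diff_step=1e-6,
        )
        params = self._make_params_fixed(spec, res.x, fixed)
        residuals = ww - spec.evaluate(params, tt)
        return res, params, residuals

    def _fixed_fields(self, init_params) -> dict:
        return {}

    def _make_params_fixed(self, spec: ModelSpec, x: np.ndarray, fixed: dict):
        if fixed:
            return spec.params_cls.from_array(x, **fixed)
        return self._make_params(spec, x)

    def predict(self, t):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "params_")
        spec = get_model(self.model_name)
        tt = _as_1d_times(t)
        return np.asarray(spec.evaluate(self.params_, tt), dtype=float)


class ExponentialRegressor(_KineticRegressorBase):
    """Single-exponential saturation fit, ``w = W_inf (1 - exp(-t/T))``."""

    model_name = "exponential"

    def _box(self, spec):
        return (np.array([0.0, 1e-6]), np.array([np.inf, np.inf]))


class GompertzRegressor(_KineticRegressorBase):
    """Modified Gompertz fit (plateau, max rate, lag)."""

    model_name = "gompertz"

    def _box(self, spec):
        return (np.array([1e-6, -np.inf, -np.inf]),
                np.array([np.inf, np.inf, np.inf]))


class LogisticRegressor(_KineticRegressorBase):
    """Logistic fit, ``w = W_inf / (1 + exp(-k t))``."""

    model_name = "logistic"

    def _box(self, spec):
        return (np.array([1e-6, 1e-6]), np.array([np.inf, np.inf]))


class GordonRegressor(_KineticRegressorBase):
    """Gordon–Govind–Green–Imam–Shogren fit.

    Sixteen coefficients and strong collinearity make this model
    ill-conditioned; explicit initial parameters are required.
    """

    model_name = "gordon"

    def __init__(self, init=None, bounds=False, tol=1e-8, max_iter=1000):
        super().__init__(init=init, bounds=bounds, tol=tol, max_iter=max_iter)

    def _resolve_init(self, spec, series):
        if self.init is None or (isinstance(self.init, str)
                                 and self.init == "heuristic"):
            raise ValueError(
                "the Gordon model requires explicit initial parameters"
            )
        return super()._resolve_init(spec, series)


class DoubleExpDelayRegressor(_KineticRegressorBase):
    """Double-exponential dead-time fit (the core model of this package).

    Parameters (beyond the shared ones)
    -----------------------------------
    w0 : float
        Baseline offset in %, held fixed during fitting (used e.g. for
        growth curves starting at a nonzero level).  When ``init`` carries
        a parameter record its ``w0`` takes precedence.
    n_starts : int
        With ``init='heuristic'``, number of candidate angular points to
        try as starting dead times; the fit with the lowest residual norm
        wins.  Under noise the largest discrete slope increase can land on
        a spike rather than on the true phase break, and this short
        multistart makes the automatic fit robust to that.  Ignored for
        explicit initial parameters.

    Examples
    --------
    >>> from biodegkin.dataio import load_fixture
    >>> fx = load_fixture("bioreactor_wastewater")
    >>> reg = DoubleExpDelayRegressor(init=fx.initial_guess).fit(fx.series)
    >>> reg.params_.tau  # doctest: +SKIP
    6.6296...
    """

    model_name = "double_exp_delay"

    def __init__(self, init="heuristic", bounds=True, tol=1e-8, max_iter=1000,
                 w0=0.0, n_starts=5):
        super().__init__(init=init, bounds=bounds, tol=tol, max_iter=max_iter)
        self.w0 = w0
        self.n_starts = n_starts

    def _initial_guesses(self, spec, series):
        if isinstance(self.init, str) and self.init == "heuristic":
            return heuristic_init_candidates(series, self.n_starts)
        return [self._resolve_init(spec, series)]

    def _box(self, spec):
        return (np.array([0.0, 1e-6, 0.0, 0.0, 1e-6]), np.full(5, np.inf))

    def _make_params(self, spec, x):
        return DoubleExpDelayParams.from_array(x, w0=self.w0)

    def _fixed_fields(self, init_params) -> dict:
        w0 = getattr(init_params, "w0", self.w0)
        return {"w0": float(w0)}


REGRESSORS = {
    "exponential": ExponentialRegressor,
    "gompertz": GompertzRegressor,
    "logistic": LogisticRegressor,
    "gordon": GordonRegressor,
    "double_exp_delay": DoubleExpDelayRegressor,
}


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_model(series: WeightLossSeries, model_name: str, init="heuristic",
              **options) -> FitResult:
    """Fit one named model to a series; returns the :class:`FitResult`."""
    reg = REGRESSORS[model_name](init=init, **options)
    reg.fit(series)
    return reg.result_


@dataclass(frozen=True)
class ComparisonEntry:
    """One row of a multi-model comparison; ``error`` is set on failure."""

    model_name: str
    fit: Optional[FitResult] = None
    panel: Optional[GoodnessOfFit] = None
    error: Optional[str] = None


def fit_all_models(
    series: WeightLossSeries,
    models: Sequence[str] = ("exponential", "gompertz", "logistic",
                             "double_exp_delay"),
    inits: Optional[Mapping[str, object]] = None,
    **options,
) -> list[ComparisonEntry]:
    """Fit several models to one series and rank them by RMSE.

    Per-model failures are captured in the returned entry rather than
    aborting the batch.  Successful fits come first, sorted by RMSE
    ascending with ties broken by fewer free parameters; failed entries
    trail in request order.
    """
    if not models:
        raise ValueError("at least one model must be requested")
    inits = dict(inits or {})
    entries: list[ComparisonEntry] = []
    for name in models:
        init = inits.get(name, "heuristic")
        try:
            fit = fit_model(series, name, init=init, **options)
            predicted = MODELS[name].evaluate(fit.params, series.times)
            panel = indicator_panel(series, predicted)
            entries.append(ComparisonEntry(name, fit=fit, panel=panel))
        except Exception as exc:  # captured per entry by contract
            entries.append(ComparisonEntry(name, error=str(exc)))
    ok = [e for e in entries if e.error is None]
    bad = [e for e in entries if e.error is not None]
    ok.sort(key=lambda e: (e.panel.rmse, MODELS[e.model_name].n_free))
    return ok + bad
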