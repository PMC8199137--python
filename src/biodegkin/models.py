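"""Closed-form kinetic models for biodegradation weight-loss profiles.

Five characteristic functions w(t) are implemented, each mapping time
(days) to percent weight loss:

* ``exponential`` — single saturating exponential,
  ``w = W_inf (1 - exp(-t/T))``.
* ``gompertz`` — modified Gompertz growth curve parameterised by the
  plateau ``W_inf``, the maximum rate ``R_m`` and the lag ``lam``.
* ``logistic`` — symmetric logistic, ``w = W_inf / (1 + exp(-k t))``.
  Note that as written this curve starts at ``W_inf/2``, not 0.
* ``gordon`` — the Gordon–Govind–Green–Imam–Shogren two-block rational
  exponential form with 16 coefficients.
* ``double_exp_delay`` — the two-phase model at the core of this package:
  two exponential saturation terms separated by a dead time ``tau``,

      w(t) = w0 + w1_inf (1 - exp(-t/T1))
                + w2_inf (1 - exp(-(t - tau)/T2)) * sigma(t - tau)

  with ``sigma`` the unit step.  The two phases track the successive loss
  of the sugar skeleton and of the (meth)acrylate network of a
  glycopolymer; ``tau`` is the adaptation lag of the microbial consortium
  before the second phase starts.  The optional baseline ``w0``
  (default 0) lets the same form describe processes that start from a
  nonzero level, e.g. a log-CFU bacterial growth curve.

Parameter records are frozen dataclasses, serialisable to and from flat
JSON dicts, and convertible to/from flat numpy vectors for fitting.

Conventions: the unit step is right-continuous, ``sigma(0) = 1`` (the
second term vanishes at ``t = tau`` either way, so this choice is
observationally neutral); time is in days throughout.  All evaluators
accept a scalar or an array of times, and grid evaluation is elementwise
identical to repeated scalar evaluation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Union

import numpy as np

__all__ = [
    "DoubleExpDelayParams",
    "ExponentialParams",
    "GompertzParams",
    "LogisticParams",
    "GordonParams",
    "eval_double_exp_delay",
    "eval_exponential",
    "eval_gompertz",
    "eval_logistic",
    "eval_gordon",
    "unit_step",
    "MODELS",
    "get_model",
]

ArrayLike = Union[float, np.ndarray]


class ParameterDomainError(ValueError):
    """A parameter value violates the model's domain (e.g. T <= 0)."""


class _ParamsBase:
    """Flat (de)serialisation shared by all parameter records."""

    def to_dict(self) -> dict:
        return {f.name: float(getattr(self, f.name)) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "_ParamsBase":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def to_array(self) -> np.ndarray:
        return np.array(
            [getattr(self, name) for name in self.free_names()], dtype=float
        )

    @classmethod
    def from_array(cls, x, **fixed) -> "_ParamsBase":
        x = np.asarray(x, dtype=float)
        names = cls.free_names()
        if x.size != len(names):
            raise ValueError(f"expected {len(names)} parameters, got {x.size}")
        return cls(**dict(zip(names, x)), **fixed)

    @classmethod
    def free_names(cls) -> tuple:
        return tuple(f.name for f in dataclasses.fields(cls))


@dataclass(frozen=True)
class ExponentialParams(_ParamsBase):
    """Single-exponential saturation: plateau ``W_inf`` (%), time constant ``T`` (days)."""

    W_inf: float
    T: float

    def __post_init__(self):
        if not self.T > 0:
            raise ParameterDomainError(f"time constant T must be > 0, got {self.T}")


@dataclass(frozen=True)
class GompertzParams(_ParamsBase):
    """Modified Gompertz curve: plateau ``W_inf`` (%), maximum rate ``R_m`` (%/day), lag ``lam`` (days)."""

    W_inf: float
    R_m: float
    lam: float

    def __post_init__(self):
        if self.W_inf == 0:
            raise ParameterDomainError("W_inf must be nonzero")


@dataclass(frozen=True)
class LogisticParams(_ParamsBase):
    """Logistic curve: plateau ``W_inf`` (%), rate constant ``k`` (1/day)."""

    W_inf: float
    k: float

    def __post_init__(self):
        if not self.W_inf > 0:
            raise ParameterDomainError(f"W_inf must be > 0, got {self.W_inf}")
        if not self.k > 0:
            raise ParameterDomainError(f"k must be > 0, got {self.k}")


@dataclass(frozen=True)
class DoubleExpDelayParams(_ParamsBase):
    """Parameters of the double-exponential dead-time model.

    Attributes
    ----------
    w1_inf : float
        First weight-loss potential (%), plateau of the fast phase.
    T1 : float
        Time constant of the fast phase (days), > 0.
    tau : float
        Dead time (days) before the second phase starts, >= 0.
    w2_inf : float
        Second weight-loss potential (%).
    T2 : float
        Time constant of the slow phase (days), > 0.
    w0 : float
        Baseline offset (%), default 0; the model supremum is
        ``w0 + w1_inf + w2_inf``.

    The canonical five-component ordering (as used for fitting vectors and
    on the command line) is ``(w1_inf, T1, tau, w2_inf, T2)``; ``w0`` is a
    fixed offset unless explicitly released.
    """

    w1_inf: float
    T1: float
    tau: float
    w2_inf: float
    T2: float
    w0: float = 0.0

    def __post_init__(self):
        if not self.T1 > 0:
            raise ParameterDomainError(f"T1 must be > 0, got {self.T1}")
        if not self.T2 > 0:
            raise ParameterDomainError(f"T2 must be > 0, got {self.T2}")
        if self.tau < 0:
            raise ParameterDomainError(f"tau must be >= 0, got {self.tau}")

    @classmethod
    def free_names(cls) -> tuple:
        # w0 is held fixed during fitting; see DoubleExpDelayRegressor.
        return ("w1_inf", "T1", "tau", "w2_inf", "T2")

    @property
    def supremum(self) -> float:
        return self.w0 + self.w1_inf + self.w2_inf


@dataclass(frozen=True)
class GordonParams(_ParamsBase):
    """Gordon–Govind–Green–Imam–Shogren two-block model (16 coefficients).

    Each block i in {1, 2} contributes

        w_inf_i * [ 1 / (a1i + a2i e^{-a3i t} + a4i e^{-a5i t^2}
                              + a6i e^{-a7i t^3})
                    - 1 / (a1i + a2i + a4i + a6i) ]

    so that w(0) = 0 exactly.  a1, a2, a4, a6 are dimensionless; a3, a5,
    a7 carry 1/day, 1/day^2 and 1/day^3.
    """

    w_inf_1: float
    a11: float
    a21: float
    a31: float
    a41: float
    a51: float
    a61: float
    a71: float
    w_inf_2: float
    a12: float
    a22: float
    a32: float
    a42: float
    a52: float
    a62: float
    a72: float

    def __post_init__(self):
        for i, (a1, a2, a4, a6) in enumerate(
            [(self.a11, self.a21, self.a41, self.a61),
             (self.a12, self.a22, self.a42, self.a62)], start=1):
            if a1 == 0:
                raise ParameterDomainError(f"a1{i} must be nonzero")
            if a1 + a2 + a4 + a6 == 0:
                raise ParameterDomainError(
                    f"a1{i}+a2{i}+a4{i}+a6{i} must be nonzero (offset term)"
                )


def unit_step(x: ArrayLike) -> ArrayLike:
    """Right-continuous unit step: 1 for x >= 0, else 0."""
    return np.where(np.asarray(x, dtype=float) >= 0.0, 1.0, 0.0)


def _as_time(t: ArrayLike) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    return t


def _maybe_scalar(out: np.ndarray, t: ArrayLike) -> ArrayLike:
    return out.item() if np.isscalar(t) or np.ndim(t) == 0 else out


def eval_double_exp_delay(params: DoubleExpDelayParams, t: ArrayLike) -> ArrayLike:
    """Evaluate the double-exponential dead-time model at time(s) ``t`` (days)."""
    tt = _as_time(t)
    first = params.w1_inf * (-np.expm1(-tt / params.T1))
    dt = tt - params.tau
    # clamp the pre-delay branch to 0 before exponentiating so that tiny T2
    # cannot overflow on the (gated-out) negative arguments
    arg = np.where(dt >= 0.0, dt, 0.0) / params.T2
    second = params.w2_inf * (-np.expm1(-arg)) * unit_step(dt)
    out = params.w0 + first + second
    return _maybe_scalar(np.asarray(out, dtype=float), t)


def eval_exponential(params: ExponentialParams, t: ArrayLike) -> ArrayLike:
    """Evaluate the single-exponential saturation model."""
    tt = _as_time(t)
    out = params.W_inf * (-np.expm1(-tt / params.T))
    return _maybe_scalar(np.asarray(out, dtype=float), t)


def eval_gompertz(params: GompertzParams, t: ArrayLike) -> ArrayLike:
    """Evaluate the modified Gompertz model."""
    tt = np.asarray(t, dtype=float)
    inner = np.e * params.R_m / params.W_inf * (params.lam - tt) + 1.0
    out = params.W_inf * np.exp(-np.exp(inner))
    return _maybe_scalar(np.asarray(out, dtype=float), t)


def eval_logistic(params: LogisticParams, t: ArrayLike) -> ArrayLike:
    """Evaluate the logistic model (note w(0) = W_inf / 2)."""
    tt = np.asarray(t, dtype=float)
    out = params.W_inf / (1.0 + np.exp(-params.k * tt))
    return _maybe_scalar(np.asarray(out, dtype=float), t)


class NumericDomainError(ArithmeticError):
    """The model is numerically undefined at some evaluated time."""


def eval_gordon(params: GordonParams, t: ArrayLike) -> ArrayLike:
    """Evaluate the Gordon–Govind–Green–Imam–Shogren model."""
    tt = _as_time(t)
    out = np.zeros_like(tt, dtype=float)
    blocks = [
        (params.w_inf_1, params.a11, params.a21, params.a31, params.a41,
         params.a51, params.a61, params.a71),
        (params.w_inf_2, params.a12, params.a22, params.a32, params.a42,
         params.a52, params.a62, params.a72),
    ]
    for w_inf, a1, a2, a3, a4, a5, a6, a7 in blocks:
        denom = (a1 + a2 * np.exp(-a3 * tt) + a4 * np.exp(-a5 * tt**2)
                 + a6 * np.exp(-a7 * tt**3))
        bad = np.atleast_1d(denom == 0.0)
        if np.any(bad):
            t_bad = np.atleast_1d(tt)[bad][0]
            raise NumericDomainError(
                f"zero denominator in Gordon model at t = {t_bad}"
            )
        out = out + w_inf * (1.0 / denom - 1.0 / (a1 + a2 + a4 + a6))
    return _maybe_scalar(np.asarray(out, dtype=float), t)


@dataclass(frozen=True)
class ModelSpec:
    """Registry entry tying a model name to its parameter type and evaluator."""

    name: str
    params_cls: type
    evaluate: Callable
    n_free: int


MODELS: dict[str, ModelSpec] = {
    "exponential": ModelSpec("exponential", ExponentialParams, eval_exponential, 2),
    "gompertz": ModelSpec("gompertz", GompertzParams, eval_gompertz, 3),
    "logistic": ModelSpec("logistic", LogisticParams, eval_logistic, 2),
    "gordon": ModelSpec("gordon", GordonParams, eval_gordon, 16),
    "double_exp_delay": ModelSpec(
        "double_exp_delay", DoubleExpDelayParams, eval_double_exp_delay, 5
    ),
}


def get_model(name: str) -> ModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; valid names: {sorted(MODELS)}"
        ) from None


def evaluate(model_name: str, params, t: ArrayLike) -> ArrayLike:
    """Evaluate a model by name; ``params`` may be a record or a flat dict."""
    spec = get_model(model_name)
    if isinstance(params, dict):
        params = spec.params_cls.from_dict(params)
    return spec.evaluate(params, t)
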