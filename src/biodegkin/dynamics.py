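"""Exogenous dynamic systems that generate weight-loss profiles.

A characteristic function w(t) can equivalently be produced as the free
response of a small dynamic system — an *exogenous* system in the
control-theoretic sense: not a physical model of the bioreactor, but a
signal generator whose natural output reproduces the observed profile.

Two such generators are implemented:

* :func:`simulate_delay_system` — a four-state linear system with a dead
  time that generates the double-exponential model.  States x1 and x3 are
  constant at 1; x2 and x4 decay exponentially from 1 with rates 1/T1 and
  1/T2 (so x2(t) = exp(-t/T1)); the output combines the delayed pair:

      w(t) = w0 + w1_inf (x1(t) - x2(t))
                + w2_inf (x3(t - tau) - x4(t - tau)) * sigma(t - tau).

  The system is formally infinite-dimensional because of the dead time,
  but x3 and x4 have closed-form histories, so the delayed terms are
  obtained by evaluating the integrator's dense output at the shifted
  time rather than running a general delay-differential solver; the two
  treatments are indistinguishable for this structure.

* :func:`simulate_logistic_system` — the first-order logistic rate law
  ``dw/dt = k w (1 - w/W_inf)``, integrated from a caller-supplied
  ``w_init``.  Started from ``w_init = W_inf/2`` its trajectory coincides
  with the closed-form logistic curve; started from exactly 0 it stays at
  0 (the origin is a fixed point), which is why a nonzero initial value
  must be supplied.

Both integrate adaptively (abs/rel tolerance 1e-10 by default, which keeps
the dense-output interpolation error comfortably below 1e-6 on these
smooth exponential states) and sample the dense solution on a
caller-chosen uniform grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .models import DoubleExpDelayParams, LogisticParams

__all__ = ["Trajectory", "simulate_delay_system", "simulate_logistic_system"]

_TOL = 1e-10


@dataclass(frozen=True)
class Trajectory:
    """A simulated output signal on a uniform time grid."""

    times: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size != v.size:
            raise ValueError("times and values must have the same length")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def to_csv(self, path) -> None:
        """Write as two-column CSV (t, w) with '#'-prefixed metadata lines."""
        with open(path, "w") as fh:
            for k, v in self.meta.items():
                fh.write(f"# {k}: {v}\n")
            fh.write("t,w\n")
            for t, w in zip(self.times, self.values):
                fh.write(f"{t:.6g},{w:.6g}\n")


def _uniform_grid(t_end: float, dt: float) -> np.ndarray:
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if dt >= t_end:
        raise ValueError(f"dt ({dt}) must be smaller than t_end ({t_end})")
    n = int(round(t_end / dt))
    return np.linspace(0.0, n * dt, n + 1)


def simulate_delay_system(
    params: DoubleExpDelayParams,
    t_end: float,
    dt: float,
    rtol: float = _TOL,
    atol: float = _TOL,
) -> Trajectory:
    """Free response of the four-state dead-time system on a uniform grid."""
    grid = _uniform_grid(t_end, dt)

    def rhs(t, x):
        return [-x[0] / params.T1, -x[1] / params.T2]

    sol = solve_ivp(
        rhs,
        (0.0, float(grid[-1])),
        [1.0, 1.0],
        method="DOP853",
        dense_output=True,
        rtol=rtol,
        atol=atol,
        # cap steps at the output spacing: once the fast state has decayed
        # the controller would otherwise take steps so long that the dense
        # interpolant degrades on the fast-decay tail
        max_step=dt,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")

    x2 = sol.sol(grid)[0]
    w = params.w0 + params.w1_inf * (1.0 - x2)
    shifted = grid - params.tau
    gate = shifted >= 0.0
    if np.any(gate):
        x4_shifted = sol.sol(np.clip(shifted, 0.0, None))[1]
        w = w + np.where(gate, params.w2_inf * (1.0 - x4_shifted), 0.0)
    meta = {
        "system": "double_exp_delay",
        "method": "DOP853",
        "rtol": rtol,
        "atol": atol,
        "dt": dt,
        "params": params.to_dict(),
    }
    return Trajectory(times=grid, values=np.asarray(w, dtype=float), meta=meta)


def simulate_logistic_system(
    params: LogisticParams,
    w_init: float,
    t_end: float,
    dt: float,
    rtol: float = _TOL,
    atol: float = _TOL,
) -> Trajectory:
    """Integrate the logistic rate law from w(0) = w_init on a uniform grid."""
    if not (0.0 < w_init <= params.W_inf):
        raise ValueError(
            f"w_init must lie in (0, W_inf] = (0, {params.W_inf}], got {w_init}"
        )
    grid = _uniform_grid(t_end, dt)

    def rhs(t, w):
        return [params.k * w[0] * (1.0 - w[0] / params.W_inf)]

    sol = solve_ivp(
        rhs,
        (0.0, float(grid[-1])),
        [float(w_init)],
        method="DOP853",
        dense_output=True,
        rtol=rtol,
        atol=atol,
        max_step=dt,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    w = sol.sol(grid)[0]
    meta = {
        "system": "logistic",
        "method": "DOP853",
        "rtol": rtol,
        "atol": atol,
        "dt": dt,
        "w_init": w_init,
        "params": params.to_dict(),
    }
    return Trajectory(times=grid, values=np.asarray(w, dtype=float), meta=meta)
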