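"""Time series container for weight-loss observations.

A biodegradation experiment is summarised by the *weight loss*

    w(t) = 100 * (m(0) - m(t)) / m(0)   [%]

measured at a handful of discrete times (days).  ``WeightLossSeries`` is the
validated in-memory form of such a record and the fitting target of every
model in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WeightLossSeries"]


@dataclass(frozen=True)
class WeightLossSeries:
    """Ordered (time, weight-loss %) observations.

    Parameters
    ----------
    times : array-like of float
        Sampling times in days; strictly increasing, ``times[0] >= 0``,
        at least two points.
    values : array-like of float
        Weight loss in percent at each time.
    label : str, optional
        Free-text identifier (dataset name, sample id, ...).
    interpolated : array-like of bool, optional
        Per-point flag marking values that were obtained by visual
        interpolation rather than direct measurement.  Defaults to all
        ``False``.
    """

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    interpolated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        w = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or w.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if t.size != w.size:
            raise ValueError(
                f"times ({t.size}) and values ({w.size}) differ in length"
            )
        if t.size < 2:
            raise ValueError("a series needs at least 2 points")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(w)):
            raise ValueError("times and values must be finite")
        if t[0] < 0:
            raise ValueError("times must start at t >= 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        flags = self.interpolated
        if flags is None:
            flags = np.zeros(t.size, dtype=bool)
        else:
            flags = np.asarray(flags, dtype=bool)
            if flags.shape != t.shape:
                raise ValueError("interpolated flags must match series length")
        t.setflags(write=False)
        w.setflags(write=False)
        flags.setflags(write=False)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", w)
        object.__setattr__(self, "interpolated", flags)

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def n(self) -> int:
        return len(self)
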